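"""Discharge quantification and screen aggregation.

The assay's readout per well is

    discharge % = (adduct area / 15N-Ub area) x ([15N] / [Ub initial]) x 100

i.e. the adduct peak area relative to a spiked, isotopically shifted
internal standard of known concentration.  For ubiquitin mutants the
standard overlaps the analyte and is omitted; there the readout is the
adduct fraction of the total observed ubiquitin signal.  Replicates are
averaged into an E2 x nucleophile heatmap, and time courses are reported
as mean +/- sample SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import ADDUCT_LABELS, MassControlList
from .peaks import (
    CalibrationError,
    Spectrum,
    calibrate,
    detect_peaks,
    estimate_baseline,
    estimate_noise,
    match_peaks,
    matched_areas,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionSpec",
    "WellResult",
    "discharge_percent",
    "discharge_fraction_no_standard",
    "process_well",
    "results_to_frame",
    "aggregate_screen",
    "time_course",
]


class EmptyWellError(ValueError):
    """No analyte or adduct signal at all in a no-standard well."""


@dataclass(frozen=True)
class ReactionSpec:
    """Design of one assay well."""

    e2_label: str
    nucleophile_label: str
    conc_ub: float = 2.0        # uM, "[Ub initial]"
    conc_standard: float = 2.0  # uM, "[15N]"
    time_min: float = 60.0
    replicate_id: int = 1
    has_standard: bool = True

    def __post_init__(self) -> None:
        if self.conc_ub <= 0:
            raise ValueError("conc_ub must be positive")
        if self.has_standard and self.conc_standard <= 0:
            raise ValueError("conc_standard must be positive when a standard is used")

    @property
    def adduct_label(self) -> str:
        return ADDUCT_LABELS.get(
            self.nucleophile_label, f"Ub-{self.nucleophile_label}"
        )


@dataclass
class WellResult:
    """Quantified outcome of one well: percent per adduct plus QC flags.

    Values above 100% are reported as-is and flagged, never clamped —
    clamping would hide calibration or response problems.
    """

    reaction: ReactionSpec
    discharge_percent: dict[str, float] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)
    calibration_shift: float = 0.0

    def __post_init__(self) -> None:
        for label, v in self.discharge_percent.items():
            if v < 0:
                raise ValueError(f"negative discharge for {label!r}")
            if v > 100.0:
                self.qc_flags.add("over_100")


def discharge_percent(
    adduct_area: float,
    standard_area: float,
    conc_standard: float,
    conc_ub: float,
) -> float:
    """(adduct area / standard area) x ([15N] / [Ub initial]) x 100."""
    if standard_area <= 0:
        raise ValueError("standard area must be positive")
    if conc_standard <= 0 or conc_ub <= 0:
        raise ValueError("concentrations must be positive")
    return (adduct_area / standard_area) * (conc_standard / conc_ub) * 100.0


def discharge_fraction_no_standard(
    adduct_areas: dict[str, float], analyte_area: float
) -> dict[str, float]:
    """Adduct fractions of the total ubiquitin signal (mutant mode).

    fraction_i = area_i / (analyte area + sum of adduct areas); together
    with the unreacted fraction these sum to one.
    """
    total = analyte_area + sum(adduct_areas.values())
    if total <= 0:
        raise EmptyWellError("no analyte or adduct signal in the well")
    return {label: area / total for label, area in adduct_areas.items()}


def process_well(
    spectrum: Spectrum,
    control_list: MassControlList,
    reaction: ReactionSpec,
    snr_threshold: float = 5.0,
    baseline_window: float = 50.0,
    saturation_level: float | None = None,
) -> WellResult:
    """Full per-well pipeline: baseline, noise, detect, calibrate, match,
    quantify.

    Failure modes become QC flags instead of dropped rows: a missing
    standard peak flags ``calibration_failed``/``standard_missing`` and
    yields no values; mutant mode (``reaction.has_standard`` False)
    reports fractions x 100 of total ubiquitin signal.
    """
    result = WellResult(reaction=reaction)
    baseline = estimate_baseline(spectrum, window=baseline_window)
    noise_sd = estimate_noise(spectrum, baseline)
    peaks = detect_peaks(spectrum, baseline, noise_sd, snr_threshold)
    if saturation_level is not None and any(
        p.apex_intensity >= saturation_level for p in peaks
    ):
        result.qc_flags.add("saturated")

    if reaction.has_standard:
        try:
            model, peaks = calibrate(peaks, control_list)
        except CalibrationError as exc:
            logger.warning("well %s/%s r%d: %s", reaction.e2_label,
                           reaction.nucleophile_label, reaction.replicate_id, exc)
            result.qc_flags |= {"calibration_failed", "standard_missing"}
            return result
        result.calibration_shift = model.shift
    else:
        result.qc_flags.add("no_standard_mode")

    peaks = match_peaks(peaks, control_list)
    areas = matched_areas(peaks, control_list)
    adduct_labels = [e.label for e in control_list if e.role == "adduct"]
    analyte_label = next(e.label for e in control_list if e.role == "analyte")

    if reaction.has_standard:
        std = control_list.standard
        if std is None or areas[std.label] <= 0:
            result.qc_flags |= {"standard_missing"}
            return result
        for label in adduct_labels:
            result.discharge_percent[label] = discharge_percent(
                areas[label], areas[std.label],
                reaction.conc_standard, reaction.conc_ub,
            )
    else:
        try:
            fractions = discharge_fraction_no_standard(
                {label: areas[label] for label in adduct_labels},
                areas[analyte_label],
            )
        except EmptyWellError:
            result.qc_flags.add("empty_well")
            return result
        for label, frac in fractions.items():
            result.discharge_percent[label] = frac * 100.0
    # re-run flagging for >100% values set after construction
    if any(v > 100.0 for v in result.discharge_percent.values()):
        result.qc_flags.add("over_100")
    return result


def results_to_frame(results: list[WellResult]) -> pd.DataFrame:
    """Tidy table: one row per (well, adduct); failed wells keep a NaN row."""
    rows = []
    for r in results:
        base = {
            "e2": r.reaction.e2_label,
            "nucleophile": r.reaction.nucleophile_label,
            "time_min": r.reaction.time_min,
            "replicate": r.reaction.replicate_id,
            "calibration_shift": r.calibration_shift,
            "flags": ";".join(sorted(r.qc_flags)),
        }
        if r.discharge_percent:
            for adduct, value in r.discharge_percent.items():
                rows.append({**base, "adduct": adduct, "discharge_percent": value})
        else:
            rows.append({**base, "adduct": r.reaction.adduct_label,
                         "discharge_percent": np.nan})
    return pd.DataFrame(rows)


def aggregate_screen(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average replicates into an E2 x nucleophile heatmap.

    Only the adduct corresponding to each well's own nucleophile enters its
    cell.  Returns (mean matrix, replicate-count matrix); cells with fewer
    than two valid replicates are reported but should be read with the
    count matrix in hand.  Failed wells (NaN) are excluded from the mean
    and from the count.
    """
    if frame.empty:
        empty = pd.DataFrame()
        return empty, empty
    own = frame[
        frame["adduct"]
        == frame["nucleophile"].map(lambda n: ADDUCT_LABELS.get(n, f"Ub-{n}"))
    ]
    valid = own.dropna(subset=["discharge_percent"])
    mean = valid.pivot_table(
        index="e2", columns="nucleophile", values="discharge_percent",
        aggfunc="mean",
    )
    counts = valid.pivot_table(
        index="e2", columns="nucleophile", values="discharge_percent",
        aggfunc="count",
    ).reindex_like(mean).fillna(0).astype(int)
    n_low = int((counts < 2).to_numpy().sum())
    if n_low:
        logger.warning("%d heatmap cell(s) have fewer than 2 valid replicates", n_low)
    return mean, counts


def time_course(frame: pd.DataFrame) -> pd.DataFrame:
    """Per (E2, nucleophile, time): replicate mean and sample SD (ddof=1).

    With a single replicate the mean is reported and the SD is left absent
    (NaN).
    """
    own = frame[
        frame["adduct"]
        == frame["nucleophile"].map(lambda n: ADDUCT_LABELS.get(n, f"Ub-{n}"))
    ].dropna(subset=["discharge_percent"])
    grouped = own.groupby(["e2", "nucleophile", "time_min"])["discharge_percent"]
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    return out.reset_index()


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the screen heatmap to a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.2 + 0.6 * matrix.shape[1], 1.0 + 0.28 * matrix.shape[0])
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="discharge (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_time_course(tc: pd.DataFrame, path) -> None:
    """Render mean +/- SD discharge curves per (E2, nucleophile) to a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (e2, nuc), sub in tc.groupby(["e2", "nucleophile"]):
        sub = sub.sort_values("time_min")
        ax.errorbar(sub["time_min"], sub["mean"], yerr=sub["sd"],
                    marker="o", capsize=3, label=f"{e2} / {nuc}")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("discharge (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
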