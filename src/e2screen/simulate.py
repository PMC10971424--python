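"""Synthetic MALDI-TOF spectrum generator with known ground truth.

The real screen's raw spectra are not deposited anywhere, so every
downstream stage is exercised on simulated linear-mode intact-protein
spectra instead: Gaussian peaks for unreacted ubiquitin (~8566 (M+H)+),
its condensation adducts, and the 15N internal standard (~8670), on an
exponentially decaying matrix baseline with additive Gaussian noise and
an optional mass-calibration offset.  Ground-truth discharge fractions
per well are carried alongside, which is what makes end-to-end parameter
recovery testable.
"""

from __future__ import annotations

import base64
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import (
    ADDUCT_LABELS,
    NUCLEOPHILES,
    STANDARD_LABEL,
    MassControlList,
    default_control_list,
)
from .peaks import Spectrum
from .quantify import ReactionSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SimulatedWell",
    "simulate_spectrum",
    "simulate_well",
    "simulate_plate",
    "write_spectrum",
    "write_plate",
    "DEFAULT_E2_PANEL",
    "TRUTH_LEVELS",
]

#: 23 human E2-conjugating enzymes screened by default (labels only).
DEFAULT_E2_PANEL = (
    "UBE2A", "UBE2B", "UBE2C", "UBE2D1", "UBE2D2", "UBE2D3", "UBE2E1",
    "UBE2G1", "UBE2G2", "UBE2H", "UBE2J2", "UBE2K", "UBE2L3", "UBE2N",
    "UBE2Q1", "UBE2Q2", "UBE2R1", "UBE2S", "UBE2T", "UBE2V1", "UBE2W",
    "UBE2Z", "UBE2QL1",
)

#: Discrete true-discharge levels used for simulated screens.
TRUTH_LEVELS = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated spectrum.

    species are (label, true_mz [Da], abundance [arbitrary units, peak
    apex height]); the calibration offset shifts every peak position to
    emulate instrument drift before internal recalibration.
    """

    species: tuple[tuple[str, float, float], ...] = ()
    peak_sigma: float = 4.0
    mz_grid: tuple[float, float, float] = (8000.0, 9200.0, 0.5)
    baseline: tuple[float, float] = (0.0, 300.0)  # (amplitude, decay length Da)
    noise_sd: float = 0.0
    calibration_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        start, stop, step = self.mz_grid
        if not (start < stop and step > 0):
            raise ValueError("mz_grid requires start < stop and step > 0")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if any(ab < 0 for _, _, ab in self.species):
            raise ValueError("abundances must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_spectrum(spec: SimulationSpec) -> Spectrum:
    """Render a spectrum: sum of Gaussians + decaying baseline + noise.

    Deterministic for a fixed ``spec`` (the seed drives the noise).
    """
    start, stop, step = spec.mz_grid
    if step > spec.peak_sigma:
        logger.warning(
            "grid step %.3g Da exceeds peak sigma %.3g Da; peaks are "
            "undersampled", step, spec.peak_sigma,
        )
    mz = np.arange(start, stop + step / 2, step)
    intensity = np.zeros_like(mz)
    for _, true_mz, abundance in spec.species:
        mu = true_mz + spec.calibration_offset
        intensity += abundance * np.exp(-0.5 * ((mz - mu) / spec.peak_sigma) ** 2)
    amp, decay = spec.baseline
    if amp:
        intensity += amp * np.exp(-(mz - start) / decay)
    if spec.noise_sd:
        rng = np.random.default_rng(spec.seed)
        intensity += rng.normal(0.0, spec.noise_sd, size=mz.size)
    return Spectrum(mz=mz, intensity=intensity)


@dataclass(frozen=True)
class GroundTruth:
    """True discharge state of one well.

    fractions: adduct label -> fraction of the ubiquitin pool converted
    (the unreacted fraction is 1 - sum).  Concentrations in uM.
    """

    fractions: dict[str, float] = field(default_factory=dict)
    conc_ub: float = 2.0
    conc_standard: float = 2.0

    def __post_init__(self) -> None:
        for label, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {label!r} outside [0, 1]: {f}")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ValueError("adduct fractions sum above 1")

    @property
    def unreacted_fraction(self) -> float:
        return 1.0 - sum(self.fractions.values())


def simulate_well(
    reaction: ReactionSpec,
    truth: GroundTruth,
    spec: SimulationSpec,
    control_list: MassControlList | None = None,
    response_per_um: float = 500.0,
) -> Spectrum:
    """Simulate one well's spectrum from its ground-truth discharge state.

    Abundances assume equal molar area response across species (the same
    assumption the ratio quantification makes): unreacted analyte scales
    with (1 - sum fractions) x [Ub], each adduct with fraction x [Ub], and
    the standard with [15N].  ``response_per_um`` converts uM to peak apex
    intensity units.
    """
    cl = default_control_list() if control_list is None else control_list
    labels = {e.label for e in cl}
    unknown = set(truth.fractions) - labels
    if unknown:
        raise ValueError(f"truth adducts not in control list: {sorted(unknown)}")

    species: list[tuple[str, float, float]] = []
    analyte = next(e for e in cl if e.role == "analyte")
    species.append(
        (analyte.label, analyte.expected_mz,
         truth.unreacted_fraction * truth.conc_ub * response_per_um)
    )
    for label, f in truth.fractions.items():
        species.append((label, cl[label].expected_mz, f * truth.conc_ub * response_per_um))
    if reaction.has_standard:
        std = cl.standard
        if std is None:
            raise ValueError("reaction declares a standard but control list has none")
        species.append((std.label, std.expected_mz, truth.conc_standard * response_per_um))
    return simulate_spectrum(replace(spec, species=tuple(species)))


@dataclass(frozen=True)
class SimulatedWell:
    well_id: str
    reaction: ReactionSpec
    truth: GroundTruth
    spectrum: Spectrum


def simulate_plate(
    e2_labels=DEFAULT_E2_PANEL,
    nucleophile_labels=tuple(NUCLEOPHILES),
    replicates: int = 2,
    time_min: float = 60.0,
    truth_levels=TRUTH_LEVELS,
    seed: int = 0,
    spec: SimulationSpec | None = None,
    control_list: MassControlList | None = None,
    conc_ub: float = 2.0,
    conc_standard: float = 2.0,
    response_per_um: float = 500.0,
    truth_overrides: dict[tuple[str, str], float] | None = None,
) -> list[SimulatedWell]:
    """Simulate a full screen plate (E2 x nucleophile grid, replicated).

    Each (E2, nucleophile) cell is assigned one true discharge level drawn
    from ``truth_levels``; technical replicates share the cell truth and
    differ only in noise and calibration drift (each well gets a small
    random offset within +/-5 Da).
    """
    rng = np.random.default_rng(seed)
    base = spec or SimulationSpec(noise_sd=1.0)
    cl = default_control_list() if control_list is None else control_list
    wells: list[SimulatedWell] = []
    for e2 in e2_labels:
        for nuc in nucleophile_labels:
            adduct = ADDUCT_LABELS.get(nuc, f"Ub-{nuc}")
            if truth_overrides and (e2, nuc) in truth_overrides:
                level = truth_overrides[(e2, nuc)]
            else:
                level = float(rng.choice(truth_levels))
            truth = GroundTruth(
                fractions={adduct: level} if level > 0 else {},
                conc_ub=conc_ub,
                conc_standard=conc_standard,
            )
            for rep in range(1, replicates + 1):
                reaction = ReactionSpec(
                    e2_label=e2,
                    nucleophile_label=nuc,
                    conc_ub=conc_ub,
                    conc_standard=conc_standard,
                    time_min=time_min,
                    replicate_id=rep,
                )
                offset = float(rng.uniform(-5.0, 5.0))
                well_spec = replace(
                    base,
                    calibration_offset=offset,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                spectrum = simulate_well(
                    reaction, truth, well_spec, cl, response_per_um
                )
                wells.append(
                    SimulatedWell(
                        well_id=f"{e2}_{nuc}_t{time_min:g}_r{rep}",
                        reaction=reaction,
                        truth=truth,
                        spectrum=spectrum,
                    )
                )
    return wells


# ---------------------------------------------------------------------------
# Output formats

_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> Path:
    """Write a spectrum as two-column XY text or single-spectrum mzML.

    The format is inferred from the extension when not given.  Round-trip
    through :func:`e2screen.peaks.read_spectrum` preserves the arrays to
    float precision.
    """
    path = Path(path)
    if len(spectrum.mz) == 0:
        raise ValueError("refusing to write an empty spectrum")
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "xy"
    format = format.lower()
    if format == "xy":
        np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]),
                   fmt="%.8g")
    elif format == "mzml":
        mz_b64 = _b64_doubles(spectrum.mz)
        int_b64 = _b64_doubles(spectrum.intensity)
        path.write_text(
            _MZML_TEMPLATE.format(
                n=len(spectrum.mz),
                mz_len=len(mz_b64), mz_b64=mz_b64,
                int_len=len(int_b64), int_b64=int_b64,
            )
        )
    else:
        raise ValueError(f"unknown spectrum format {format!r}")
    return path


def write_plate(
    wells: list[SimulatedWell], outdir, format: str = "xy"
) -> Path:
    """Write a simulated plate: one spectrum file per well plus a manifest.

    The manifest CSV carries the reaction design and the ground truth for
    each well, which is everything quantification and recovery checks need.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".mzML" if format.lower() == "mzml" else ".xy"
    rows = []
    for well in wells:
        fname = well.well_id + ext
        write_spectrum(well.spectrum, outdir / fname, format)
        truth_adduct = max(well.truth.fractions, default="",
                           key=lambda k: well.truth.fractions[k])
        rows.append(
            {
                "well": well.well_id,
                "file": fname,
                "e2": well.reaction.e2_label,
                "nucleophile": well.reaction.nucleophile_label,
                "time_min": well.reaction.time_min,
                "replicate": well.reaction.replicate_id,
                "conc_ub_um": well.reaction.conc_ub,
                "conc_standard_um": well.reaction.conc_standard,
                "has_standard": well.reaction.has_standard,
                "truth_adduct": truth_adduct,
                "truth_fraction": sum(well.truth.fractions.values()),
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
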