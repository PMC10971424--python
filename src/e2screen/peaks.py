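"""Spectrum -> calibrated, control-list-matched peaks.

Processing contract of the screen: estimate the baseline (rolling minimum
followed by rolling mean), estimate the noise level robustly, detect peaks
at a signal-to-noise threshold of 5, recalibrate all centroids by a single
additive shift anchored on the 15N-ubiquitin internal standard, and match
the calibrated peaks to the expected-m/z control list.  Peak *areas*, not
apex heights, feed quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import savgol_filter

from .chemistry import MassControlList

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Peak",
    "CalibrationModel",
    "CalibrationError",
    "read_spectrum",
    "estimate_baseline",
    "estimate_noise",
    "detect_peaks",
    "calibrate",
    "match_peaks",
    "matched_areas",
    "peaks_to_frame",
]


class CalibrationError(RuntimeError):
    """No usable internal-standard peak; the well cannot be calibrated."""


@dataclass(frozen=True)
class Spectrum:
    """A profile-mode m/z-intensity trace on a strictly ascending grid."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.ndim != 1 or mz.shape != intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly ascending")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def step(self) -> float:
        """Median grid spacing, Da."""
        return float(np.median(np.diff(self.mz)))


@dataclass(frozen=True)
class Peak:
    centroid_mz: float
    apex_intensity: float
    area: float
    snr: float
    matched_label: str | None = None

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Single-point internal recalibration: one additive m/z shift.

    One anchor peak determines only an offset, so the model is additive by
    construction; the residual at the anchor is zero after correction.
    """

    shift: float
    anchor_label: str | None
    residual: float = 0.0

    def apply(self, mz):
        return np.asarray(mz, dtype=float) + self.shift


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum from two-column XY text or mzML (via pyteomics)."""
    path = Path(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "xy"
    format = format.lower()
    if format == "xy":
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (m/z, intensity)")
        return Spectrum(mz=data[:, 0], intensity=data[:, 1])
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def _read_mzml(path) -> Spectrum:
    """Minimal mzML reader: first spectrum's m/z and intensity arrays.

    Handles 32/64-bit float arrays, optionally zlib-compressed, by their
    PSI-MS cvParam accessions.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    tree = ET.parse(path)
    for node in tree.iter():
        if local(node.tag) != "spectrum":
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in node.iter():
            if local(bda.tag) != "binaryDataArray":
                continue
            accessions = {
                child.get("accession")
                for child in bda
                if local(child.tag) == "cvParam"
            }
            binary = next(
                (c for c in bda.iter() if local(c.tag) == "binary"), None
            )
            if binary is None or binary.text is None:
                continue
            raw = base64.b64decode(binary.text)
            if "MS:1000574" in accessions:  # zlib compression
                raw = zlib.decompress(raw)
            dtype = "<f4" if "MS:1000521" in accessions else "<f8"
            values = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accessions:
                arrays["mz"] = values
            elif "MS:1000515" in accessions:
                arrays["intensity"] = values
        if "mz" in arrays and "intensity" in arrays:
            return Spectrum(mz=arrays["mz"], intensity=arrays["intensity"])
    raise ValueError(f"{path}: no spectrum with m/z and intensity arrays found")


def estimate_baseline(spectrum: Spectrum, window: float = 50.0) -> np.ndarray:
    """Baseline trace: rolling minimum then rolling mean over ``window`` Da.

    The rolling minimum drops below peaks (they are narrow relative to the
    window); the rolling mean smooths the staircase the minimum leaves.
    """
    step = spectrum.step
    if window <= step:
        raise ValueError(f"window ({window} Da) must exceed the grid step ({step} Da)")
    span = spectrum.mz[-1] - spectrum.mz[0]
    if window >= span:
        raise ValueError(f"window ({window} Da) must be below the m/z range ({span} Da)")
    size = max(3, int(round(window / step)) | 1)  # odd so the filter is centered
    floor = minimum_filter1d(spectrum.intensity, size=size, mode="nearest")
    return uniform_filter1d(floor, size=size, mode="nearest")


def estimate_noise(
    spectrum: Spectrum,
    baseline: np.ndarray | None = None,
    max_iter: int = 10,
) -> float:
    """Robust noise SD: 1.4826 x MAD of the residual over peak-free points.

    Points exceeding 3x the current estimate are masked and the estimate is
    recomputed until stable, so peaks do not inflate it.
    """
    if len(spectrum) <= 50:
        raise ValueError("noise estimation needs more than 50 points")
    residual = spectrum.intensity - (0.0 if baseline is None else baseline)
    mask = np.ones(residual.size, dtype=bool)
    sd = np.inf
    for _ in range(max_iter):
        sel = residual[mask]
        if sel.size == 0:
            raise ValueError("all points masked as peaks; cannot estimate noise")
        centered = sel - np.median(sel)
        new_sd = 1.4826 * float(np.median(np.abs(centered)))
        if new_sd == 0.0:
            return 0.0
        new_mask = np.abs(residual - np.median(sel)) <= 3.0 * new_sd
        if new_sd >= sd * (1 - 1e-6):
            return new_sd
        sd, mask = new_sd, new_mask
    return sd


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima of ``y``."""
    return np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1


def _half_max_region(y: np.ndarray, apex: int) -> tuple[int, int]:
    """Contiguous [lo, hi] index range around ``apex`` with y >= apex/2."""
    half = y[apex] / 2.0
    lo = apex
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = apex
    while hi < y.size - 1 and y[hi + 1] >= half:
        hi += 1
    return lo, hi


def detect_peaks(
    spectrum: Spectrum,
    baseline: np.ndarray | None = None,
    noise_sd: float | None = None,
    snr_threshold: float = 5.0,
    smooth_window: int | None = None,
    merge_shoulder_frac: float = 0.5,
) -> list[Peak]:
    """Detect peaks in the baseline-subtracted trace at a S/N threshold.

    Apexes are strict local maxima whose baseline-subtracted height is at
    least ``snr_threshold`` x ``noise_sd``.  A maximum is absorbed into a
    taller one when the valley between them stays above
    ``merge_shoulder_frac`` of the smaller apex (it is a shoulder, not a
    resolved peak); for resolved peaks this never triggers.  Per peak:
    centroid = intensity-weighted mean m/z over the contiguous region above
    half the apex; area = trapezoidal integral between the flanking minima
    separating it from neighbouring accepted peaks, truncated to +/-4
    sigma-hat (sigma-hat from the half-max width).

    ``smooth_window`` (odd point count) applies an optional quadratic
    Savitzky-Golay filter before detection; off by default.
    """
    if noise_sd is None:
        noise_sd = estimate_noise(spectrum, baseline)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = spectrum.intensity - (0.0 if baseline is None else baseline)
    if smooth_window:
        y = savgol_filter(y, smooth_window, polyorder=2)
    floor = snr_threshold * noise_sd
    candidates = [i for i in _local_maxima(y) if y[i] >= floor and y[i] > 0]
    if not candidates:
        return []

    # Shoulder merging: visit apexes tallest-first; keep one only if it is
    # separated from every already-kept apex by a deep enough valley.
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: -y[i]):
        absorbed = False
        for j in kept:
            lo, hi = min(i, j), max(i, j)
            valley = y[lo : hi + 1].min()
            if valley >= merge_shoulder_frac * min(y[i], y[j]):
                absorbed = True
                break
        if not absorbed:
            kept.append(i)
    kept.sort()

    mz = spectrum.mz
    peaks: list[Peak] = []
    for k, apex in enumerate(kept):
        lo_half, hi_half = _half_max_region(y, apex)
        seg_y = y[lo_half : hi_half + 1]
        seg_mz = mz[lo_half : hi_half + 1]
        centroid = float(np.average(seg_mz, weights=seg_y))
        fwhm = float(mz[hi_half] - mz[lo_half]) or spectrum.step
        sigma_hat = fwhm / 2.3548

        # Integration bounds: minima toward adjacent accepted peaks
        # (spectrum edges otherwise), then the +/-4 sigma-hat window if
        # that is narrower.
        left_lim = kept[k - 1] if k > 0 else 0
        right_lim = kept[k + 1] if k + 1 < len(kept) else y.size - 1
        lo = left_lim + int(np.argmin(y[left_lim : apex + 1])) if apex > left_lim else apex
        hi = apex + int(np.argmin(y[apex : right_lim + 1])) if right_lim > apex else apex
        lo = max(lo, int(np.searchsorted(mz, centroid - 4 * sigma_hat)))
        hi = min(hi, int(np.searchsorted(mz, centroid + 4 * sigma_hat)))
        hi = max(hi, lo + 1)
        area = float(np.trapezoid(y[lo : hi + 1], mz[lo : hi + 1]))
        snr = float(y[apex] / noise_sd) if noise_sd > 0 else float("inf")
        peaks.append(
            Peak(
                centroid_mz=centroid,
                apex_intensity=float(y[apex]),
                area=max(area, 0.0),
                snr=snr,
            )
        )
    return peaks


def calibrate(
    peaks: list[Peak],
    control_list: MassControlList,
    search_window: float = 20.0,
) -> tuple[CalibrationModel, list[Peak]]:
    """Single-point internal recalibration on the standard entry.

    The detected peak nearest the expected standard m/z (within
    ``search_window``; ties broken toward the larger area) anchors an
    additive shift applied to every centroid.  Without a standard entry
    (ubiquitin-mutant mode) the model is the identity.
    """
    std = control_list.standard
    if std is None:
        logger.info("control list has no standard entry; calibration is identity")
        model = CalibrationModel(shift=0.0, anchor_label=None)
        return model, list(peaks)
    candidates = [p for p in peaks if abs(p.centroid_mz - std.expected_mz) <= search_window]
    if not candidates:
        raise CalibrationError(
            f"no peak within +/-{search_window} Da of the standard "
            f"{std.label} ({std.expected_mz:.1f})"
        )
    anchor = min(
        candidates,
        key=lambda p: (abs(p.centroid_mz - std.expected_mz), -p.area),
    )
    shift = std.expected_mz - anchor.centroid_mz
    model = CalibrationModel(shift=shift, anchor_label=std.label)
    shifted = [replace(p, centroid_mz=p.centroid_mz + shift) for p in peaks]
    return model, shifted


def match_peaks(
    peaks: list[Peak], control_list: MassControlList
) -> list[Peak]:
    """Assign calibrated peaks to control entries by global nearest m/z.

    Candidate (entry, peak) pairs within the match tolerance are processed
    in ascending |delta m/z|; each entry claims at most one peak and each
    peak serves at most one entry.  Within-float ties go to the lower-m/z
    entry (with a warning).
    """
    pairs = []
    for entry in control_list:
        for idx, p in enumerate(peaks):
            delta = abs(p.centroid_mz - entry.expected_mz)
            if delta <= control_list.match_tolerance:
                pairs.append((delta, entry.expected_mz, entry.label, idx))
    tied = {
        (a[0], a[3]) for a in pairs for b in pairs
        if a[3] == b[3] and a[2] != b[2] and abs(a[0] - b[0]) < 1e-9
    }
    if tied:
        logger.warning(
            "%d peak(s) equidistant from two control entries; assigned to "
            "the lower-m/z entry", len(tied),
        )
    pairs.sort()
    claimed_entries: set[str] = set()
    claimed_peaks: set[int] = set()
    assignment: dict[int, str] = {}
    for _, _, label, idx in pairs:
        if label in claimed_entries or idx in claimed_peaks:
            continue
        claimed_entries.add(label)
        claimed_peaks.add(idx)
        assignment[idx] = label
    return [
        replace(p, matched_label=assignment.get(i)) for i, p in enumerate(peaks)
    ]


def matched_areas(
    peaks: list[Peak], control_list: MassControlList
) -> dict[str, float]:
    """Area per control-list label; unmatched entries report zero area."""
    areas = {entry.label: 0.0 for entry in control_list}
    for p in peaks:
        if p.matched_label is not None:
            areas[p.matched_label] = p.area
    return areas


def peaks_to_frame(peaks: list[Peak], calibration: CalibrationModel | None = None):
    """Tidy per-spectrum peak table (pandas DataFrame)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "centroid_mz": p.centroid_mz,
                "apex_intensity": p.apex_intensity,
                "area": p.area,
                "snr": p.snr,
                "matched_label": p.matched_label,
                "calibration_shift": calibration.shift if calibration else 0.0,
            }
            for p in peaks
        ]
    )
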