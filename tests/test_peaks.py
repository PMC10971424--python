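"""Peak processing: baseline, noise, S/N-gated detection, calibration,
control-list matching."""

import numpy as np
import pytest

from e2screen import chemistry as chem
from e2screen.peaks import (
    CalibrationError,
    Peak,
    Spectrum,
    calibrate,
    detect_peaks,
    estimate_baseline,
    estimate_noise,
    match_peaks,
    matched_areas,
)

from conftest import brute_force_apexes, gaussian_spectrum


def flat_spectrum(value, n=2400, start=8000.0, step=0.5):
    mz = start + step * np.arange(n)
    return Spectrum(mz=mz, intensity=np.full(n, float(value)))


class TestBaseline:
    def test_flat_spectrum_baseline_is_the_constant(self):
        s = flat_spectrum(7.5)
        assert np.allclose(estimate_baseline(s, window=50.0), 7.5)

    def test_baseline_under_isolated_peak_is_near_zero(self):
        s = gaussian_spectrum([8600.0], [100.0])
        baseline = estimate_baseline(s, window=80.0)
        under = baseline[(s.mz > 8580) & (s.mz < 8620)]
        assert np.all(under <= 1.0)  # <= 1% of the apex

    def test_exponential_baseline_recovered_within_5_percent(self):
        decay = 400.0
        s = gaussian_spectrum([], [], baseline=lambda m: 50.0 * np.exp(-(m - 8000.0) / decay))
        est = estimate_baseline(s, window=30.0)
        true = 50.0 * np.exp(-(s.mz - 8000.0) / decay)
        interior = slice(60, -60)  # edge-mode artifacts excluded
        assert np.all(np.abs(est[interior] - true[interior]) <= 0.05 * true[interior])

    def test_window_wider_than_range_rejected(self):
        s = flat_spectrum(1.0, n=100)
        with pytest.raises(ValueError):
            estimate_baseline(s, window=1e5)

    def test_window_below_step_rejected(self):
        s = flat_spectrum(1.0)
        with pytest.raises(ValueError):
            estimate_baseline(s, window=0.1)


class TestNoise:
    def test_pure_gaussian_noise_recovered(self):
        rng = np.random.default_rng(0)
        mz = 8000 + 0.5 * np.arange(4000)
        s = Spectrum(mz=mz, intensity=rng.normal(0, 1.0, mz.size))
        assert 0.9 <= estimate_noise(s) <= 1.1

    def test_noise_free_trace_gives_zero(self):
        s = flat_spectrum(3.0)
        baseline = estimate_baseline(s, window=50.0)
        assert estimate_noise(s, baseline) == 0.0

    def test_tall_peak_does_not_inflate_estimate(self):
        s = gaussian_spectrum([8600.0], [500.0], noise_sd=5.0, seed=1)
        assert 4.5 <= estimate_noise(s) <= 5.5

    def test_short_spectrum_rejected(self):
        s = flat_spectrum(1.0, n=40)
        with pytest.raises(ValueError):
            estimate_noise(s)


class TestDetect:
    def test_zero_trace_gives_no_peaks(self):
        s = flat_spectrum(0.0)
        assert detect_peaks(s, noise_sd=1.0) == []

    def test_single_gaussian_with_injected_noise_floor(self):
        s = gaussian_spectrum([8600.0], [100.0])
        peaks = detect_peaks(s, noise_sd=1.0)
        assert len(peaks) == 1
        assert abs(peaks[0].centroid_mz - 8600.0) <= s.step
        assert peaks[0].snr == pytest.approx(100.0, rel=1e-6)

    def test_subthreshold_peak_suppressed(self):
        s = gaussian_spectrum([8400.0, 8800.0], [100.0, 3.0], noise_sd=1.0, seed=2)
        peaks = detect_peaks(s, noise_sd=1.0, snr_threshold=5.0)
        assert len(peaks) == 1
        assert abs(peaks[0].centroid_mz - 8400.0) < 2.0

    def test_area_matches_gaussian_closed_form(self):
        sigma, amp = 4.0, 100.0
        s = gaussian_spectrum([8600.0], [amp], sigma=sigma)
        (peak,) = detect_peaks(s, noise_sd=1.0)
        assert peak.area == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_matches_brute_force_oracle_on_small_grids(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n_peaks = rng.integers(0, 4)
            centers = np.sort(8500 + 100 * rng.random(n_peaks) * 0.9)
            if len(centers):
                centers = centers[np.r_[True, np.diff(centers) > 25]]  # resolved
            amps = rng.uniform(10, 100, len(centers))
            s = gaussian_spectrum(centers, amps, sigma=3.0,
                                  grid=(8500.0, 8600.0, 0.5))
            peaks = detect_peaks(s, noise_sd=1.0, snr_threshold=5.0)
            oracle = brute_force_apexes(s.intensity, 1.0, 5.0)
            assert sorted(p.apex_intensity for p in peaks) == pytest.approx(
                sorted(s.intensity[i] for i in oracle)
            )

    def test_raising_threshold_never_adds_peaks(self):
        s = gaussian_spectrum([8300.0, 8600.0, 8900.0], [100.0, 20.0, 7.0],
                              noise_sd=1.0, seed=3)
        previous = None
        for thr in (3.0, 5.0, 10.0, 30.0):
            current = {
                round(p.centroid_mz, 6)
                for p in detect_peaks(s, noise_sd=1.0, snr_threshold=thr)
            }
            if previous is not None:
                assert current <= previous
            previous = current

    def test_area_scales_exactly_with_intensity(self):
        s = gaussian_spectrum([8400.0, 8700.0], [80.0, 40.0], noise_sd=1.0, seed=4)
        k = 3.0
        scaled = Spectrum(mz=s.mz, intensity=k * s.intensity)
        p1 = detect_peaks(s, noise_sd=1.0)
        p2 = detect_peaks(scaled, noise_sd=k * 1.0)
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            assert b.area == pytest.approx(k * a.area, rel=1e-12)


def make_control_list():
    return chem.default_control_list()


class TestCalibrate:
    def test_offset_recovered(self):
        cl = make_control_list()
        std_mz = cl.standard.expected_mz
        s = gaussian_spectrum([std_mz + 3.0, 8565.9 + 3.0], [100.0, 100.0])
        peaks = detect_peaks(s, noise_sd=1.0)
        model, shifted = calibrate(peaks, cl)
        assert model.shift == pytest.approx(-3.0, abs=s.step)
        residual = min(abs(p.centroid_mz - std_mz) for p in shifted)
        assert residual < 1e-9 or residual <= s.step

    def test_zero_offset_identity(self):
        cl = make_control_list()
        s = gaussian_spectrum([cl.standard.expected_mz], [100.0])
        peaks = detect_peaks(s, noise_sd=1.0)
        model, _ = calibrate(peaks, cl)
        assert abs(model.shift) <= s.step

    def test_calibration_is_idempotent(self):
        cl = make_control_list()
        s = gaussian_spectrum([cl.standard.expected_mz + 4.0], [100.0])
        peaks = detect_peaks(s, noise_sd=1.0)
        _, once = calibrate(peaks, cl)
        model2, twice = calibrate(once, cl)
        assert model2.shift == pytest.approx(0.0, abs=1e-9)
        assert [p.centroid_mz for p in twice] == pytest.approx(
            [p.centroid_mz for p in once]
        )

    def test_no_standard_peak_raises(self):
        cl = make_control_list()
        s = gaussian_spectrum([8400.0], [100.0])
        peaks = detect_peaks(s, noise_sd=1.0)
        with pytest.raises(CalibrationError):
            calibrate(peaks, cl)

    def test_no_standard_entry_gives_identity_model(self):
        cl = chem.build_mass_control_list(nucleophiles=["Ac-T"],
                                          standard_nitrogen=None)
        peaks = [Peak(8600.0, 10.0, 100.0, 10.0)]
        model, out = calibrate(peaks, cl)
        assert model.shift == 0.0 and model.anchor_label is None
        assert out == peaks


class TestMatch:
    def test_peak_claims_nearest_entry(self):
        cl = make_control_list()
        peaks = [Peak(8735.5, 10.0, 50.0, 10.0)]
        out = match_peaks(peaks, cl)
        assert out[0].matched_label == "Ub-K"

    def test_no_peaks_all_entries_zero_area(self):
        cl = make_control_list()
        areas = matched_areas(match_peaks([], cl), cl)
        assert set(areas) == {e.label for e in cl}
        assert all(v == 0.0 for v in areas.values())

    def test_equidistant_peak_goes_to_lower_mz_entry(self, caplog):
        import logging

        cl = chem.MassControlList(
            entries=[
                chem.ControlEntry("low", 1000.0, "analyte"),
                chem.ControlEntry("high", 1008.0, "adduct"),
            ],
            match_tolerance=5.0,
        )
        peaks = [Peak(1004.0, 10.0, 5.0, 10.0)]
        with caplog.at_level(logging.WARNING, logger="e2screen.peaks"):
            out = match_peaks(peaks, cl)
        assert out[0].matched_label == "low"
        assert "equidistant" in caplog.text

    def test_one_peak_serves_at_most_one_entry(self):
        cl = chem.MassControlList(
            entries=[
                chem.ControlEntry("a", 1000.0, "analyte"),
                chem.ControlEntry("b", 1003.0, "adduct"),
            ],
            match_tolerance=5.0,
        )
        peaks = [Peak(1001.0, 10.0, 5.0, 10.0), Peak(1003.5, 8.0, 4.0, 8.0)]
        out = match_peaks(peaks, cl)
        assert [p.matched_label for p in out] == ["a", "b"]

    def test_out_of_tolerance_peak_unmatched(self):
        cl = make_control_list()
        out = match_peaks([Peak(8000.0, 10.0, 5.0, 10.0)], cl)
        assert out[0].matched_label is None


def test_spectrum_validation():
    with pytest.raises(ValueError):
        Spectrum(mz=np.array([1.0, 1.0, 2.0]), intensity=np.zeros(3))
    with pytest.raises(ValueError):
        Spectrum(mz=np.array([1.0]), intensity=np.array([0.0]))
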