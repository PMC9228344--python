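"""Cross-scan aggregation, offsets, FSD marking and the censoring
correction."""

import numpy as np
import pytest

from scancentric import characterize as ch
from scancentric.centroid import ScanPeak
from scancentric.synth import default_model


def make_scan_peaks(centers, log_heights, region="R0"):
    return [ScanPeak(scan_id=f"s{k}", center_freq=c, center_mz=np.nan,
                     log_height=lh, height=float(np.exp(lh)), area=1.0,
                     ssr=0.0, n_points=9, region_id=region)
            for k, (c, lh) in enumerate(zip(centers, log_heights))]


def pooled_gaussian(center, apex, n_scans):
    p = np.arange(center - 5.0, center + 5.01, 0.5)
    pos, inten = [], []
    for _ in range(n_scans):
        pos.append(p)
        inten.append(apex * np.exp(-0.5 * ((p - center) / 1.5) ** 2))
    return np.concatenate(pos), np.concatenate(inten)


def make_peak(peak_id, scan_log_heights, n_total, fsd=0.0):
    n = len(scan_log_heights)
    return ch.CharacterizedPeak(
        peak_id=peak_id, center_freq_fit=0.0, center_mz_fit=0.0,
        center_freq_mean=0.0, center_freq_sd=fsd, height_fit=1.0,
        height_mean=float(np.exp(list(scan_log_heights.values())).mean())
        if scan_log_heights else 0.0,
        height_sd=0.0, n_scans=n, scan_fraction=n / n_total,
        scan_log_heights=dict(scan_log_heights))


class TestAggregate:
    def test_identical_scans_pool_to_scan_mean(self):
        center = 1000.0
        sp = make_scan_peaks([center] * 10, [13.0] * 10)
        peak = ch.aggregate_peak("R0", pooled_gaussian(center, 1e6, 10), sp,
                                 n_total_scans=10, model=default_model())
        assert peak.center_freq_fit == pytest.approx(center, abs=1e-9)
        assert peak.center_freq_mean == center
        assert peak.center_freq_sd == 0.0
        assert peak.scan_fraction == 1.0
        assert peak.center_mz_fit == pytest.approx(
            (1e7 / center) ** 2, rel=1e-9)

    def test_single_scan_flagged_low_replication(self):
        sp = make_scan_peaks([1000.0], [13.0])
        peak = ch.aggregate_peak("R0", pooled_gaussian(1000.0, 1e6, 1), sp,
                                 n_total_scans=10)
        assert peak.n_scans == 1
        assert peak.height_sd == 0.0 and peak.center_freq_sd == 0.0
        assert peak.flags["low_replication"]

    def test_lognormal_height_dispersion_recovered(self):
        rng = np.random.default_rng(15)
        sigma = 0.2
        lh = 13.0 + rng.normal(0, sigma, 50)
        sp = make_scan_peaks([1000.0] * 50, lh)
        peak = ch.aggregate_peak("R0", pooled_gaussian(1000.0, 4e5, 50), sp,
                                 n_total_scans=50)
        cv = peak.height_sd / peak.height_mean
        assert cv == pytest.approx(np.sqrt(np.exp(sigma ** 2) - 1),
                                   rel=0.10)

    def test_empty_region_none(self):
        assert ch.aggregate_peak("R0", (np.array([]), np.array([])), [],
                                 n_total_scans=10) is None


class TestOffset:
    def test_matches_derivative_oracle(self):
        model = default_model()  # mz = 1e14 / f^2
        for mz in (200.0, 400.0, 800.0):
            f = 1e7 / np.sqrt(mz)
            analytic = 2e14 / f ** 3 * 0.5   # |dmz/df| * spacing
            got = ch.compute_offset(model, f, 0.5)
            assert got == pytest.approx(analytic, rel=1e-4)

    def test_offset_grows_with_mz(self):
        model = default_model()
        freqs = 1e7 / np.sqrt(np.linspace(200.0, 900.0, 20))
        offs = [ch.compute_offset(model, f, 0.5) for f in freqs]
        assert all(a < b for a, b in zip(offs, offs[1:]))

    def test_zero_spacing_guarded(self):
        with pytest.raises(ValueError):
            ch.compute_offset(default_model(), 5e5, 0.0)


class TestHighFsd:
    def test_gross_outlier_marked(self):
        peaks = [make_peak(f"p{i}", {"s0": 10.0, "s1": 10.1}, 2, fsd=0.1)
                 for i in range(20)]
        peaks.append(make_peak("hot", {"s0": 10.0, "s1": 10.1}, 2, fsd=5.0))
        thr = ch.mark_high_fsd(peaks)
        assert thr is not None
        assert peaks[-1].flags.get("high_fsd") is True
        assert not any(p.flags.get("high_fsd") for p in peaks[:-1])

    def test_equal_fsds_none_marked(self):
        peaks = [make_peak(f"p{i}", {"s0": 10.0, "s1": 10.0}, 2, fsd=0.2)
                 for i in range(10)]
        ch.mark_high_fsd(peaks)
        assert not any(p.flags.get("high_fsd") for p in peaks)

    def test_under_four_peaks_skipped(self):
        peaks = [make_peak(f"p{i}", {"s0": 1.0, "s1": 2.0}, 2, fsd=float(i))
                 for i in range(3)]
        assert ch.mark_high_fsd(peaks) is None


class TestCensoringCorrection:
    S = 20

    def calibration_peaks(self, rng, n=30, sigma=0.5):
        out = []
        for i in range(n):
            mu = rng.uniform(10, 14)
            vals = rng.normal(mu, sigma, self.S)
            out.append(make_peak(
                f"cal{i}", {f"s{k}": float(v)
                            for k, v in enumerate(vals)}, self.S))
        return out

    def test_full_presence_correction_is_identity_like(self):
        rng = np.random.default_rng(16)
        peaks = self.calibration_peaks(rng)
        ch.correct_height_sd(peaks, self.S, rng=1)
        for p in peaks:
            obs_sd = np.std(list(p.scan_log_heights.values()), ddof=1)
            assert p.height_sd_corrected == pytest.approx(obs_sd, rel=1e-12)
            # censored-normal MLE with nothing censored is the plain mean
            mu = np.mean(list(p.scan_log_heights.values()))
            assert np.log(p.height_mean_corrected) == pytest.approx(
                mu, abs=1e-6)

    def test_corrected_mean_beats_raw_under_censoring(self):
        rng = np.random.default_rng(42)
        peaks = self.calibration_peaks(rng)
        truths, tests = [], []
        for i in range(60):
            mu = rng.uniform(8, 12)
            vals = rng.normal(mu, 0.5, self.S)
            censor = mu - 0.125          # ~40% left-censoring
            obs = vals[vals >= censor]
            if obs.size < 3:
                continue
            p = make_peak(f"t{i}", {f"s{k}": float(v)
                                    for k, v in enumerate(obs)}, self.S)
            truths.append(mu)
            tests.append(p)
        ch.correct_height_sd(peaks + tests, self.S, rng=1)
        wins = sum(
            abs(np.log(p.height_mean_corrected) - mu)
            < abs(np.mean(list(p.scan_log_heights.values())) - mu)
            for mu, p in zip(truths, tests))
        assert wins / len(tests) >= 0.8

    def test_cubic_matches_independent_resampling_estimate(self):
        rng = np.random.default_rng(17)
        peaks = self.calibration_peaks(rng, n=40)
        coefs = ch.correct_height_sd(peaks, self.S, rng=5)
        poly = np.poly1d(coefs)
        # independent oracle: fresh RNG, more draws, direct ratio estimate
        H = np.array([[p.scan_log_heights[f"s{k}"] for k in range(self.S)]
                      for p in peaks])
        full_sd = H.std(axis=1, ddof=1)
        oracle_rng = np.random.default_rng(999)
        for frac in (0.25, 0.5, 0.75):
            k = max(2, round(frac * self.S))
            est = np.mean([
                np.mean(H[:, oracle_rng.choice(self.S, k, replace=False)]
                        .std(axis=1, ddof=1) / full_sd)
                for _ in range(500)])
            assert poly(frac) == pytest.approx(est, abs=0.05)

    def test_too_few_calibration_peaks_skips(self):
        rng = np.random.default_rng(18)
        peaks = self.calibration_peaks(rng, n=5)
        assert ch.correct_height_sd(peaks, self.S, rng=1) is None
        assert all(p.height_mean_corrected is None for p in peaks)
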