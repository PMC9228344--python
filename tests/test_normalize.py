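"""Scan-to-scan normalization: peak selection, reference choice, factors,
scan-order correlation and the two-pass modes."""

import numpy as np
import pandas as pd
import pytest

from scancentric import normalize as nm


def matrix(values, scans=None, peaks=None):
    df = pd.DataFrame(values)
    if scans is not None:
        df.columns = scans
    if peaks is not None:
        df.index = peaks
    return df


def full_matrix(n_peaks, n_scans, rng=None, base=12.0, spread=3.0):
    rng = np.random.default_rng(rng)
    mu = rng.uniform(base - spread, base + spread, n_peaks)
    return pd.DataFrame(np.tile(mu[:, None], (1, n_scans)),
                        columns=[f"s{j}" for j in range(n_scans)])


class TestSelection:
    def test_presence_percentile(self):
        rng = np.random.default_rng(1)
        H = full_matrix(100, 10, rng=2)
        # knock peaks out of scans so presence counts vary 5..10
        counts = rng.integers(5, 11, 100)
        for i in range(100):
            out = rng.choice(10, size=10 - counts[i], replace=False)
            H.iloc[i, out] = np.nan
        mask = nm.select_normalization_peaks(H, intensity_filter=False,
                                             min_peaks_per_scan=1)
        thresh = np.percentile(H.notna().sum(axis=1), 95)
        keep = H.notna().sum(axis=1) >= thresh
        assert set(H.index[mask.any(axis=1)]) == set(H.index[keep])

    def test_intensity_filter_on_log_heights(self):
        H = full_matrix(30, 4, rng=3)
        H.iloc[0] = 20.0  # dominant peak
        mask = nm.select_normalization_peaks(H, intensity_filter=True,
                                             min_peaks_per_scan=1)
        expected = H.ge(0.7 * H.max(axis=0), axis=1)
        assert (mask == expected).all().all()

    def test_under_25_peaks_is_fatal(self):
        H = full_matrix(24, 5, rng=4)
        with pytest.raises(nm.NormalizationError, match="25"):
            nm.select_normalization_peaks(H, intensity_filter=False)


class TestReferenceScan:
    def test_identical_scans_tie_to_first(self):
        H = full_matrix(30, 3, rng=5)
        assert nm.choose_reference_scan(H) == "s0"

    def test_midpoint_scan_wins(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(10, 14, 40)
        H = matrix({"A": a, "B": a + 0.5, "C": a + 1.0})
        assert nm.choose_reference_scan(H) == "B"

    def test_two_scans_earliest(self):
        H = full_matrix(30, 2, rng=7)
        assert nm.choose_reference_scan(H) == "s0"


class TestFactors:
    def test_doubled_scan_gets_ln2(self):
        a = np.random.default_rng(8).uniform(10, 14, 30)
        H = matrix({"A": a, "B": a + np.log(2.0)})
        fac = nm.compute_factors(H, "A")
        assert fac["A"] == 0.0
        assert fac["B"] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_heterogeneous_shifts_match_bruteforce_median(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(10, 14, 21)
        shifts = rng.normal(0.3, 0.2, 21)
        H = matrix({"A": a, "B": a + shifts})
        fac = nm.compute_factors(H, "A")
        assert fac["B"] == pytest.approx(np.median(shifts), abs=1e-12)

    def test_disjoint_scan_dropped(self):
        H = matrix({"A": [10.0, 11.0, np.nan, np.nan],
                    "B": [10.5, 11.5, np.nan, np.nan],
                    "C": [np.nan, np.nan, 9.0, 9.5]})
        fac = nm.compute_factors(H, "A")
        assert np.isnan(fac["C"])


class TestScanCorrelation:
    def test_strictly_increasing_flagged(self):
        H = matrix({f"s{j}": [10.0 + 0.1 * j] for j in range(6)},
                   peaks=["p"])
        assert nm.detect_scan_correlated_peaks(H) == ["p"]

    def test_constant_not_flagged(self):
        H = matrix({f"s{j}": [10.0] for j in range(6)}, peaks=["p"])
        assert nm.detect_scan_correlated_peaks(H) == []

    def test_negative_correlation_flagged_by_absolute_value(self):
        rng = np.random.default_rng(10)
        vals = 12.0 - 0.2 * np.arange(8) + rng.normal(0, 0.05, 8)
        assert abs(np.corrcoef(np.arange(8), vals)[0, 1]) > 0.5
        H = matrix({f"s{j}": [vals[j]] for j in range(8)}, peaks=["p"])
        assert nm.detect_scan_correlated_peaks(H) == ["p"]

    def test_under_three_observations_not_evaluated(self):
        H = matrix({"s0": [10.0], "s1": [11.0], "s2": [np.nan]},
                   peaks=["p"])
        assert nm.detect_scan_correlated_peaks(H) == []


class TestTwoPass:
    def shifted_matrix(self, factors, n_peaks=40, rng=11):
        g = np.random.default_rng(rng)
        mu = g.uniform(11, 13, n_peaks)
        return pd.DataFrame(
            {f"s{j}": mu + f for j, f in enumerate(factors)})

    def test_nonorm_identity(self):
        H = self.shifted_matrix([0.0, 0.4, -0.2])
        res = nm.two_pass_normalize(H, "nonorm")
        assert (res.factors == 0.0).all()

    def test_exact_shift_recovery_all_modes(self):
        truth = np.array([0.0, 0.3, -0.3, 0.15, -0.1])
        H = self.shifted_matrix(truth)
        for mode in ("singlenorm", "singlenorm_int", "doublenorm"):
            res = nm.two_pass_normalize(H, mode)
            ref = list(H.columns).index(res.reference_scan)
            got = res.factors.to_numpy()
            assert np.allclose(got, truth - truth[ref], atol=1e-9), mode

    def test_post_normalization_median_difference_zero(self):
        rng = np.random.default_rng(12)
        truth = rng.normal(0, 0.3, 6)
        H = self.shifted_matrix(truth) + \
            rng.normal(0, 0.2, (40, 6))
        res = nm.two_pass_normalize(H, "doublenorm")
        normalized = H.sub(res.factors, axis=1)
        used = [p for p in res.used_peaks]
        for col in H.columns:
            med = (normalized.loc[used, col]
                   - normalized.loc[used, res.reference_scan]).median()
            assert abs(med) < 1e-12

    def test_translation_equivariance(self):
        rng = np.random.default_rng(13)
        H = self.shifted_matrix(rng.normal(0, 0.3, 5)) + \
            rng.normal(0, 0.1, (40, 5))
        res1 = nm.two_pass_normalize(H, "doublenorm")
        res2 = nm.two_pass_normalize(H + np.log(7.0), "doublenorm")
        assert np.allclose(res1.factors.to_numpy(),
                           res2.factors.to_numpy(), atol=1e-12)

    def test_correlated_peaks_excluded_from_second_pass(self):
        rng = np.random.default_rng(14)
        truth = rng.normal(0, 0.2, 8)
        H = self.shifted_matrix(truth, n_peaks=40)
        H.iloc[0] = 12.0 + 0.5 * np.arange(8)  # scan-trending artifact
        res = nm.two_pass_normalize(H, "doublenorm")
        assert H.index[0] in res.scan_correlated_peaks
        assert H.index[0] not in res.used_peaks
        assert not set(res.scan_correlated_peaks) & set(res.used_peaks)
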