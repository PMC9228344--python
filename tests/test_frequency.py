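"""Proxy-frequency derivation, model fitting and axis conversion."""

import numpy as np
import pytest

from scancentric import frequency as fq
from scancentric.scan_io import ProfileScan, ScanSet
from scancentric.synth import default_model


def make_scan(mz, intensity=None, scan_id="s0"):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return ProfileScan(scan_id=scan_id, rt=0.0, ms_level=1, mz=mz,
                       intensity=intensity)


class TestProxyFrequency:
    def test_adjacent_pair_arithmetic(self):
        proxy = fq.derive_proxy_frequency(make_scan([200.000, 200.001]))
        assert proxy.freq.size == 1  # 2-point scan -> exactly one triple
        assert proxy.mid_mz[0] == pytest.approx(200.0005, abs=1e-12)
        assert proxy.freq[0] == pytest.approx(200000.5, rel=1e-9)

    def test_duplicate_mz_pairs_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            proxy = fq.derive_proxy_frequency(
                make_scan([100.0, 100.0, 100.1, 100.2]))
        assert proxy.freq.size == 2
        assert proxy.n_dropped_pairs == 1

    def test_single_point_scan_rejected(self):
        with pytest.raises(fq.ScanFitError):
            fq.derive_proxy_frequency(make_scan([400.0]))

    def test_uniform_grid_recovers_true_frequency(self):
        # grid synthesized from a known inverse model: proxy frequency must
        # match the generating frequency to 1e-6 relative
        model = default_model()
        f = 505000.0 - 0.5 * np.arange(4000)
        mz = np.asarray(fq.frequency_to_mz(model, f))
        proxy = fq.derive_proxy_frequency(make_scan(mz))
        true_mid = 0.5 * (f[:-1] + f[1:])
        assert np.allclose(proxy.freq, true_mid, rtol=1e-6)


class TestDiffSummary:
    def test_constant_half_gives_mode_half_and_2pct_band(self):
        s = fq.summarize_frequency_diffs([0.5] * 1000)
        assert s.mode_diff == pytest.approx(0.5, abs=1e-12)
        assert s.lo == pytest.approx(0.49, abs=1e-12)
        assert s.hi == pytest.approx(0.51, abs=1e-12)
        assert s.n_useful == 1000

    def test_mode_is_majority_bin(self):
        diffs = [0.5] * 1000 + [7.3] * 5
        s = fq.summarize_frequency_diffs(diffs)
        assert s.mode_diff == pytest.approx(0.5, abs=0.0051)
        assert s.n_useful == 1000

    def test_zero_tolerance_collapses_band(self):
        s = fq.summarize_frequency_diffs([0.5] * 10, tol=0.0)
        assert s.lo == s.hi == s.mode_diff

    def test_empty_is_fatal(self):
        with pytest.raises(ValueError):
            fq.summarize_frequency_diffs([])


class TestModelFit:
    def test_exact_sqrt_law_recovery(self):
        mz = np.linspace(150.0, 1000.0, 5000)
        freq = 1e7 / np.sqrt(mz)
        m = fq.fit_mz_frequency(mz, freq)
        assert m.y == pytest.approx(1e7, rel=1e-6)
        # the other terms vanish relative to the sqrt term's contribution
        f_scale = freq.mean()
        assert abs(m.a) < 1e-6 * f_scale
        assert abs(m.x / mz.mean()) < 1e-6 * f_scale
        assert abs(m.z * mz.mean() ** (-1 / 3)) < 1e-6 * f_scale
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_frequency_is_pure_intercept(self):
        mz = np.linspace(200.0, 800.0, 100)
        m = fq.fit_mz_frequency(mz, np.full(100, 123.0))
        assert m.a == pytest.approx(123.0, abs=1e-6)
        assert abs(m.x) < 1e-4 and abs(m.y) < 1e-4 and abs(m.z) < 1e-4

    def test_noisy_recovery_within_one_percent(self):
        a, x, y, z = -2e5, 2e7, 2.93e7, -3e6
        mz = np.linspace(150.0, 1000.0, 1_000_000)
        truth = a + x / mz + y / np.sqrt(mz) + z / np.cbrt(mz)
        rng = np.random.default_rng(4)
        freq = truth * (1 + rng.normal(0, 1e-3, mz.size))
        m = fq.fit_mz_frequency(mz, freq)
        got = np.array([m.a, m.x, m.y, m.z])
        assert np.all(np.abs(got / np.array([a, x, y, z]) - 1) < 0.01)

    def test_too_few_distinct_mz_is_fatal(self):
        with pytest.raises(fq.ScanFitError, match="rank-deficient"):
            fq.fit_mz_frequency([400.0, 400.0, 500.0, 500.0],
                                [1.0, 1.0, 2.0, 2.0])

    def test_scan_level_fit_needs_enough_useful_points(self):
        model = default_model()
        f = 505000.0 - 0.5 * np.arange(8)
        mz = np.asarray(fq.frequency_to_mz(model, f))
        with pytest.raises(fq.ScanFitError, match="useful"):
            fq.fit_frequency_model(make_scan(mz))


def model_with_y(y, scan_id):
    return fq.FrequencyModel(a=0, x=0, y=y, z=0, inv_a=0, inv_x=0,
                             inv_y=y * y, inv_z=0, source_scan=scan_id)


class TestMasterSelection:
    def test_median_pick(self):
        models = [model_with_y(v, i) for i, v in enumerate([9.9, 10.0, 10.4])]
        assert fq.select_master_model(models).source_scan == 1

    def test_single_scan(self):
        m = model_with_y(5.0, "only")
        assert fq.select_master_model([m]) is m

    def test_even_count_tie_breaks_to_earliest(self):
        models = [model_with_y(v, i) for i, v in enumerate([1.0, 2.0, 3.0,
                                                            4.0])]
        # median 2.5; y=2 and y=3 equidistant -> earliest wins
        assert fq.select_master_model(models).source_scan == 1


class TestOutlierScans:
    def test_gross_outlier_flagged(self):
        models = [model_with_y(v, i)
                  for i, v in enumerate([10, 10, 10, 10, 30])]
        assert fq.detect_outlier_scans(models) == [4]

    def test_identical_coefficients_no_flags(self):
        models = [model_with_y(10.0, i) for i in range(6)]
        assert fq.detect_outlier_scans(models) == []

    def test_fewer_than_four_scans_skipped(self):
        models = [model_with_y(v, i) for i, v in enumerate([1, 2, 100])]
        assert fq.detect_outlier_scans(models) == []


class TestConversion:
    def test_closed_form(self):
        m = model_with_y(1e7, 0)
        assert fq.mz_to_frequency(m, 400.0) == pytest.approx(5e5)
        assert fq.frequency_to_mz(m, 5e5) == pytest.approx(400.0)

    @pytest.mark.parametrize("func", [fq.mz_to_frequency, fq.frequency_to_mz])
    def test_nonpositive_inputs_fatal(self, func):
        with pytest.raises(ValueError):
            func(model_with_y(1e7, 0), -1.0)

    def test_monotone_decreasing_over_fitted_range(self, desk_run):
        _, _, _, result = desk_run
        mz = np.linspace(341.0, 479.0, 10_000)
        f = fq.mz_to_frequency(result.master_model, mz)
        assert np.all(np.diff(f) < 0)

    def test_roundtrip_below_microThomson(self, desk_run):
        _, _, _, result = desk_run
        mz = np.linspace(341.0, 479.0, 10_000)
        back = fq.frequency_to_mz(
            result.master_model,
            np.asarray(fq.mz_to_frequency(result.master_model, mz)))
        assert np.max(np.abs(back - mz)) < 1e-6


class TestOrderPreservation:
    def test_fitted_master_model_passes(self, desk_run):
        _, scanset, _, result = desk_run
        report = fq.check_order_preservation(scanset, result.master_model)
        assert report.ok

    def test_non_monotone_model_fails(self):
        # a model whose frequency curve increases with m/z reverses ordering
        bad = fq.FrequencyModel(a=0, x=0, y=-1e7, z=0, inv_a=0, inv_x=0,
                                inv_y=1e14, inv_z=0)
        scan = make_scan(np.linspace(400.0, 401.0, 50))
        report = fq.check_order_preservation(
            ScanSet(scans=[scan]), bad)
        assert not report.ok
        assert report.violations

    def test_single_point_scan_trivially_passes(self):
        report = fq.check_order_preservation(
            ScanSet(scans=[make_scan([400.0])]), model_with_y(1e7, 0))
        assert report.ok
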