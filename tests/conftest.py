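"""Shared fixtures: desk-scale synthetic acquisitions.

The desk fixtures use the generator's default noise/intensity conditions
over a narrower m/z window (340-480 Th, ~86k frequency units, ~172k grid
points per scan) so that full pipeline runs stay in the seconds range while
preserving the spectral structure (clustered peaks, mostly signal-free
density tiles).
"""

from __future__ import annotations

import numpy as np
import pytest

from scancentric import pipeline, synth
from scancentric.frequency import frequency_to_mz, mz_to_frequency

DESK_MZ_RANGE = (340.0, 480.0)


def desk_spec(**overrides) -> synth.SyntheticSpec:
    overrides.setdefault("mz_range", DESK_MZ_RANGE)
    overrides.setdefault("seed", 42)
    return synth.SyntheticSpec(**overrides)


def clustered_peaks(model, n, rng, mz_range=DESK_MZ_RANGE, cluster_size=8,
                    cluster_width=300.0, height_log10=(6.0, 8.0)):
    """Explicit clustered peak list mirroring the generator's layout."""
    f_lo = mz_to_frequency(model, mz_range[1])
    f_hi = mz_to_frequency(model, mz_range[0])
    span = f_hi - f_lo
    margin = 0.03 * span
    n_cl = max(1, -(-n // cluster_size))
    cl_lo = np.linspace(f_lo + margin, f_hi - margin - cluster_width, n_cl)
    peaks = []
    for i in range(n):
        c, j = divmod(i, cluster_size)
        n_in = min(cluster_size, n - c * cluster_size)
        step = cluster_width / n_in
        f = cl_lo[c] + (j + 0.5) * step + rng.uniform(-0.2, 0.2) * step
        peaks.append(synth.SyntheticPeak(
            mz=float(frequency_to_mz(model, f)),
            height=float(10.0 ** rng.uniform(*height_log10))))
    return peaks


@pytest.fixture(scope="session")
def desk_run():
    """Default-condition desk acquisition run in filtersd mode."""
    spec = desk_spec(seed=7)
    scanset, truth = synth.generate_scanset(spec)
    result = pipeline.run(pipeline.PipelineConfig(mode="filtersd"), scanset)
    return spec, scanset, truth, result


@pytest.fixture(scope="session")
def artifact_runs():
    """Artifact-laden acquisition (scan-trending + high-jitter peaks) run in
    every processing mode."""
    spec = desk_spec(seed=42, n_trend_peaks=12, n_hpd_peaks=8)
    scanset, truth = synth.generate_scanset(spec)
    results = {mode: pipeline.run(pipeline.PipelineConfig(mode=mode),
                                  scanset)
               for mode in pipeline.MODES}
    return spec, scanset, truth, results


@pytest.fixture(scope="session")
def hpd_run():
    """20-scan acquisition with 8 injected high-jitter (HPD-like) peaks
    among 60 clean ones, filtersd mode."""
    spec = desk_spec(seed=42, n_scans=20, n_hpd_peaks=8)
    scanset, truth = synth.generate_scanset(spec)
    result = pipeline.run(pipeline.PipelineConfig(mode="filtersd"), scanset)
    return spec, scanset, truth, result


def trend_norm_spec(seed=42):
    """Normalization-ordering fixture: 110 clean high-intensity peaks plus
    40 scan-trending ones (30 below, 10 above the intensity-filter
    threshold), low lognormal noise so the artifact bias is observable."""
    model = synth.default_model()
    rng = np.random.default_rng(seed + 1000)
    peaks = clustered_peaks(model, 150, rng)
    for i in range(110, 140):
        peaks[i] = synth.SyntheticPeak(
            mz=peaks[i].mz, height=float(10.0 ** rng.uniform(4.5, 5.5)),
            trend_slope=-0.15)
    for i in range(140, 150):
        peaks[i] = synth.SyntheticPeak(
            mz=peaks[i].mz, height=peaks[i].height, trend_slope=-0.15)
    return synth.SyntheticSpec(model=model, mz_range=DESK_MZ_RANGE,
                               seed=seed, peaks=peaks, peak_noise_sd=0.02)


@pytest.fixture(scope="session")
def trend_norm_runs():
    spec = trend_norm_spec()
    scanset, truth = synth.generate_scanset(spec)
    results = {mode: pipeline.run(pipeline.PipelineConfig(mode=mode),
                                  scanset)
               for mode in ("singlenorm", "singlenorm_int", "doublenorm")}
    return spec, scanset, truth, results


def factor_rmse(result, truth):
    """RMSE of recovered normalization factors against ln truth factors,
    aligned at the reference scan."""
    fac = result.normalization.factors
    tr = np.log(truth.scan_factors)
    scan_index = {f"s{k:03d}": k for k in range(len(tr))}
    ref_k = scan_index[result.normalization.reference_scan]
    errs = [float(fac[sid]) - (tr[scan_index[sid]] - tr[ref_k])
            for sid in fac.index]
    return float(np.sqrt(np.mean(np.square(errs))))
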