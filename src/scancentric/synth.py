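"""Synthetic multi-scan Fusion-like profile spectra with known ground truth.

The generator emulates the error structure of direct-infusion Orbitrap
profile data: a uniform frequency grid (adjacent-point difference 0.5 by
default) mapped to m/z through a known frequency model; peaks rendered as
Gaussians in frequency (hence exactly log-parabolic — the fixed point of
the centroiding model, so recovery has an analytic truth); multiplicative
scan-to-scan intensity factors; per-peak lognormal scan noise; a constant
additive noise component; instrument-style flooring of everything below a
detection threshold (producing the zero baseline and low-peak dropout);
sparse random single-point noise spikes; and two artifact classes — peaks
whose height trends with scan order, and high-peak-density-like peaks whose
center jitter is inflated (x10 by default).

It is not a physical Orbitrap transient simulator: no image current, no FT
artifacts, no real isotope fine structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .frequency import FrequencyModel, frequency_to_mz, mz_to_frequency
from .scan_io import ProfileScan, ScanSet

__all__ = ["SyntheticPeak", "SyntheticSpec", "SyntheticTruth",
           "RecoveryReport", "default_model", "isotopologue_peaks",
           "generate_scanset", "truth_report"]


def default_model(y: float = 1.0e7) -> FrequencyModel:
    """Fusion-like pure-sqrt model f = y/sqrt(mz); at m/z 400 the frequency
    is 5e5 and a 0.5 frequency grid step corresponds to ~0.8 mTh."""
    return FrequencyModel.sqrt_model(y, source_scan="synthetic")


@dataclass
class SyntheticPeak:
    mz: float
    height: float                # base apex intensity, arbitrary units
    nap: float | None = None     # natural abundance probability, optional
    group: object = None         # isotopologue group id, optional
    trend_slope: float = 0.0     # d ln(height) / d scan index
    jitter_scale: float = 1.0    # 1 = normal; ~10 = HPD-like artifact


def isotopologue_peaks(mz: float, height: float, naps, group=None,
                       delta_mz: float = 1.003355) -> list:
    """Isotopologue series: peak k at mz + k*delta_mz with height
    height * nap_k / nap_0."""
    naps = list(naps)
    return [SyntheticPeak(mz=mz + k * delta_mz,
                          height=height * naps[k] / naps[0],
                          nap=naps[k], group=group)
            for k in range(len(naps))]


@dataclass
class SyntheticSpec:
    """Generator conditions.  Defaults mirror the printed magnitudes of
    Fusion acquisitions: 0.5 frequency spacing, m/z 150-1000, peak heights
    1e4-1e8, instrument floor ~1e3."""

    model: FrequencyModel = field(default_factory=default_model)
    mz_range: tuple = (150.0, 1000.0)
    spacing: float = 0.5
    n_scans: int = 10
    peaks: list | None = None            # explicit SyntheticPeak list
    n_peaks: int = 60                    # used when peaks is None
    cluster_size: int = 8                # peaks per cluster (isotopologue-
    cluster_width: float = 300.0         # like grouping, frequency units)
    height_log10_range: tuple = (4.0, 8.0)
    scan_factor_sd: float = 0.2          # sd of ln scan factors
    peak_noise_sd: float = 0.25          # lognormal per-peak-per-scan noise
    center_jitter_sd: float = 0.05       # frequency units
    sigma_freq: float = 1.5              # Gaussian peak width, freq units
    dropout_threshold: float = 1.0e3     # instrument floor
    additive_noise_sd: float = 200.0
    noise_rate: float = 10.0             # spikes per 1000 freq units per scan
    n_trend_peaks: int = 0
    trend_slope: float = -0.12
    n_hpd_peaks: int = 0
    hpd_jitter_scale: float = 10.0
    rt_start: float = 10.0
    rt_step: float = 5.0
    seed: int = 0


@dataclass
class SyntheticTruth:
    model: FrequencyModel
    peaks: list                          # SyntheticPeak
    peak_freqs: np.ndarray               # true centers, frequency units
    scan_factors: np.ndarray             # multiplicative, raw space
    scan_centers: np.ndarray             # (n_peaks, n_scans) jittered centers
    scan_apexes: np.ndarray              # (n_peaks, n_scans) pre-floor apexes
    detected: np.ndarray                 # apex >= dropout_threshold
    dropout_threshold: float
    noise_rate: float
    spacing: float
    seed: int


def _build_peaks(spec: SyntheticSpec, rng) -> list:
    if spec.peaks is not None:
        return list(spec.peaks)
    model = spec.model
    f_hi = mz_to_frequency(model, spec.mz_range[0])
    f_lo = mz_to_frequency(model, spec.mz_range[1])
    span = f_hi - f_lo
    margin = 0.03 * span
    n_main = spec.n_peaks
    lg = rng.uniform(*spec.height_log10_range, size=n_main)
    # peaks come in isotopologue-like clusters so that most density tiles
    # are signal-free, as in real direct-infusion spectra; within a
    # cluster, evenly spaced slots with a small random offset keep peak
    # regions separated
    n_clusters = max(1, -(-n_main // spec.cluster_size))
    cluster_lo = np.linspace(f_lo + margin,
                             f_hi - margin - spec.cluster_width, n_clusters)
    centers = []
    for k in range(n_main):
        c, j = divmod(k, spec.cluster_size)
        n_in = min(spec.cluster_size, n_main - c * spec.cluster_size)
        step = spec.cluster_width / n_in
        centers.append(cluster_lo[c] + (j + 0.5) * step
                       + rng.uniform(-0.2, 0.2) * step)
    centers = np.asarray(centers)
    peaks = [SyntheticPeak(mz=float(frequency_to_mz(model, c)),
                           height=float(10.0 ** h))
             for c, h in zip(centers, lg)]
    idx = rng.choice(n_main, size=min(spec.n_trend_peaks, n_main),
                     replace=False)
    for i in idx:
        peaks[i] = replace(peaks[i], trend_slope=spec.trend_slope)
    if spec.n_hpd_peaks:
        hpd_lo = f_lo + 0.45 * span
        hpd_centers = hpd_lo + (np.arange(spec.n_hpd_peaks) + 0.5) \
            * 1000.0 / spec.n_hpd_peaks
        lg_h = rng.uniform(5.5, 7.5, size=spec.n_hpd_peaks)
        peaks.extend(
            SyntheticPeak(mz=float(frequency_to_mz(spec.model, c)),
                          height=float(10.0 ** h),
                          jitter_scale=spec.hpd_jitter_scale)
            for c, h in zip(hpd_centers, lg_h))
    return peaks


def generate_scanset(spec: SyntheticSpec):
    """Render the spectra; returns (ScanSet, SyntheticTruth).

    Bit-identical under a fixed spec (single RNG, fixed draw order).
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    lo_mz, hi_mz = spec.mz_range
    if lo_mz >= hi_mz:
        raise ValueError("invalid m/z range")
    f_hi = mz_to_frequency(model, lo_mz)
    f_lo = mz_to_frequency(model, hi_mz)
    n_grid = int(np.floor((f_hi - f_lo) / spec.spacing)) + 1
    f_grid = f_hi - spec.spacing * np.arange(n_grid)      # descending
    mz_grid = np.asarray(frequency_to_mz(model, f_grid))  # ascending
    peaks = _build_peaks(spec, rng)
    for p in peaks:
        if not (lo_mz < p.mz < hi_mz):
            raise ValueError(f"peak at m/z {p.mz} outside range {spec.mz_range}")
    peak_freqs = np.array([mz_to_frequency(model, p.mz) for p in peaks])
    S, P = spec.n_scans, len(peaks)
    scan_factors = np.exp(rng.normal(0.0, spec.scan_factor_sd, size=S))
    scan_centers = np.empty((P, S))
    scan_apexes = np.empty((P, S))
    span_units = f_hi - f_lo
    half = (S - 1) / 2.0
    scans = []
    for s in range(S):
        inten = (rng.normal(0.0, spec.additive_noise_sd, size=n_grid)
                 if spec.additive_noise_sd > 0 else np.zeros(n_grid))
        for k, p in enumerate(peaks):
            jitter = rng.normal(0.0, spec.center_jitter_sd * p.jitter_scale) \
                if spec.center_jitter_sd > 0 else 0.0
            c = peak_freqs[k] + jitter
            noise = rng.normal(0.0, spec.peak_noise_sd) \
                if spec.peak_noise_sd > 0 else 0.0
            apex = (p.height * scan_factors[s]
                    * np.exp(p.trend_slope * (s - half)) * np.exp(noise))
            scan_centers[k, s] = c
            scan_apexes[k, s] = apex
            # f_grid descends: index grows as frequency falls
            i0 = int(np.ceil((f_hi - (c + 6 * spec.sigma_freq))
                             / spec.spacing))
            i1 = int(np.floor((f_hi - (c - 6 * spec.sigma_freq))
                              / spec.spacing))
            i0, i1 = max(i0, 0), min(i1, n_grid - 1)
            if i1 < i0:
                continue
            fw = f_grid[i0:i1 + 1]
            inten[i0:i1 + 1] += apex * np.exp(
                -0.5 * ((fw - c) / spec.sigma_freq) ** 2)
        n_spikes = rng.poisson(spec.noise_rate * span_units / 1000.0) \
            if spec.noise_rate > 0 else 0
        if n_spikes:
            idx = rng.integers(0, n_grid, size=n_spikes)
            inten[idx] += 10.0 ** rng.uniform(3.0, 4.5, size=n_spikes)
        inten = np.where(inten < spec.dropout_threshold, 0.0, inten)
        scans.append(ProfileScan(scan_id=f"s{s:03d}",
                                 rt=spec.rt_start + s * spec.rt_step,
                                 ms_level=1, mz=mz_grid.copy(),
                                 intensity=inten))
    truth = SyntheticTruth(model=model, peaks=peaks, peak_freqs=peak_freqs,
                           scan_factors=scan_factors,
                           scan_centers=scan_centers,
                           scan_apexes=scan_apexes,
                           detected=scan_apexes >= spec.dropout_threshold,
                           dropout_threshold=spec.dropout_threshold,
                           noise_rate=spec.noise_rate, spacing=spec.spacing,
                           seed=spec.seed)
    return ScanSet(scans=scans, sample_id=f"synthetic-{spec.seed}",
                   provenance={"generator": "scancentric.synth",
                               "seed": spec.seed}), truth


@dataclass
class RecoveryReport:
    matched: "np.ndarray"            # bool per true peak
    center_errors: "np.ndarray"      # freq units, NaN when unmatched
    height_log_errors: "np.ndarray"  # ln(found mean) - ln(true), NaN unmatched
    n_scans_found: "np.ndarray"
    false_positives: int
    recall: float
    hpd_flag_recall: float
    clean_false_flag_rate: float


def truth_report(truth: SyntheticTruth, characterized,
                 tol_freq: float = 3.0) -> RecoveryReport:
    """Match characterized peaks to true peak loci (nearest center within
    ``tol_freq`` frequency units) and score recovery plus the high-FSD
    flagging of the injected high-jitter artifacts."""
    P = len(truth.peaks)
    matched = np.zeros(P, dtype=bool)
    center_err = np.full(P, np.nan)
    height_err = np.full(P, np.nan)
    n_found = np.zeros(P, dtype=int)
    flagged = np.zeros(P, dtype=bool)
    used = set()
    if characterized:
        found = np.array([c.center_freq_fit for c in characterized])
        for k in range(P):
            d = np.abs(found - truth.peak_freqs[k])
            j = int(np.argmin(d))
            if d[j] <= tol_freq:
                matched[k] = True
                used.add(j)
                c = characterized[j]
                center_err[k] = float(found[j] - truth.peak_freqs[k])
                height_err[k] = float(np.log(c.height_mean)
                                      - np.log(truth.peaks[k].height))
                n_found[k] = c.n_scans
                flagged[k] = bool(c.flags.get("high_fsd", False))
    is_hpd = np.array([p.jitter_scale > 1.0 for p in truth.peaks])
    hpd_matched = matched & is_hpd
    clean_matched = matched & ~is_hpd
    return RecoveryReport(
        matched=matched,
        center_errors=center_err,
        height_log_errors=height_err,
        n_scans_found=n_found,
        false_positives=len(characterized) - len(used),
        recall=float(matched.mean()) if P else float("nan"),
        hpd_flag_recall=(float(flagged[is_hpd].mean())
                         if is_hpd.any() else float("nan")),
        clean_false_flag_rate=(float(flagged[clean_matched].mean())
                               if clean_matched.any() else 0.0),
    )
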