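"""Cross-scan peak aggregation, offsets, FSD flagging and the experimental
height/SD censoring correction.

Each peak region's normalized, non-zero raw points from all contributing
scans are pooled and re-fitted with the weighted parabolic model, giving the
final center and height.  Scan-level centroid statistics give the mean/SD of
the center in frequency units (the FSD) and of the height in raw space.
High-peak-density artifact survivors present as peaks with outlying FSD and
are marked (never removed).

The censoring correction estimates how much the across-scan SD shrinks when
a peak is only detected in a fraction of scans (left-censoring at the
instrument's detection floor), by subsampling the heights of peaks present
in all scans, and then re-estimates the mean under a left-censored normal
model of natural-log heights.  It is retained as an experimental feature:
downstream comparisons favor the raw scan-centric intensities, so the
corrected values are reported alongside, never instead of, the raw ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .centroid import fit_weighted_parabola
from .frequency import FrequencyModel, frequency_to_mz

__all__ = ["CharacterizedPeak", "aggregate_peak", "compute_offset",
           "mark_high_fsd", "correct_height_sd"]

log = logging.getLogger(__name__)


@dataclass
class CharacterizedPeak:
    peak_id: object
    center_freq_fit: float
    center_mz_fit: float
    center_freq_mean: float
    center_freq_sd: float          # FSD
    height_fit: float
    height_mean: float
    height_sd: float
    n_scans: int
    scan_fraction: float
    offset_mz: float = float("nan")
    height_mean_corrected: float | None = None
    height_sd_corrected: float | None = None
    area_mean: float = float("nan")
    flags: dict = field(default_factory=dict)
    # internal: natural-log normalized scan-level heights, kept for the
    # censoring correction and QC metrics
    scan_log_heights: dict = field(default_factory=dict, repr=False)

    def to_dict(self, with_scan_heights: bool = False) -> dict:
        d = {
            "peak_id": self.peak_id,
            "center_freq_fit": self.center_freq_fit,
            "center_mz_fit": self.center_mz_fit,
            "center_freq_mean": self.center_freq_mean,
            "center_freq_sd": self.center_freq_sd,
            "height_fit": self.height_fit,
            "height_mean": self.height_mean,
            "height_sd": self.height_sd,
            "n_scans": self.n_scans,
            "scan_fraction": self.scan_fraction,
            "offset_mz": self.offset_mz,
            "height_mean_corrected": self.height_mean_corrected,
            "height_sd_corrected": self.height_sd_corrected,
            "area_mean": self.area_mean,
            "flags": dict(self.flags),
        }
        if with_scan_heights:
            d["scan_log_heights"] = dict(self.scan_log_heights)
        return d


def aggregate_peak(peak_id, pooled_points, scan_peaks, n_total_scans: int,
                   model: FrequencyModel | None = None,
                   c: float = 1.0,
                   multi_peak_discards: int = 0):
    """Characterize one peak region across scans.

    ``pooled_points`` is (freq positions, normalized intensities) pooled over
    contributing scans (non-zero points only); ``scan_peaks`` the accepted
    per-scan ScanPeak list with normalized log heights.  Returns None when
    the pooled fit is not concave (peak dropped, logged).
    """
    if not scan_peaks:
        return None
    pos, inten = pooled_points
    fit = fit_weighted_parabola(pos, inten, c=c)
    if fit is None:
        log.info("peak %s dropped: pooled fit not concave", peak_id)
        return None
    centers = np.array([p.center_freq for p in scan_peaks])
    log_h = np.array([p.log_height for p in scan_peaks])
    heights = np.exp(log_h)
    areas = np.array([p.area for p in scan_peaks])
    n = len(scan_peaks)
    flags = {"low_replication": n == 1,
             "multi_peak_discarded_scans": int(multi_peak_discards),
             "high_fsd": False, "scan_correlated": False}
    return CharacterizedPeak(
        peak_id=peak_id,
        center_freq_fit=fit["center"],
        center_mz_fit=(frequency_to_mz(model, fit["center"])
                       if model is not None else float("nan")),
        center_freq_mean=float(centers.mean()),
        center_freq_sd=float(centers.std(ddof=1)) if n > 1 else 0.0,
        height_fit=fit["height"],
        height_mean=float(heights.mean()),
        height_sd=float(heights.std(ddof=1)) if n > 1 else 0.0,
        n_scans=n,
        scan_fraction=n / float(n_total_scans),
        area_mean=float(areas.mean()),
        flags=flags,
        scan_log_heights={p.scan_id: float(p.log_height)
                          for p in scan_peaks},
    )


def compute_offset(model: FrequencyModel, center_freq: float,
                   spacing: float) -> float:
    """Half-spacing search offset in Th: |mz(center - spacing) - mz(center)|
    where ``spacing`` is the median frequency point-to-point difference of
    the model-usable points."""
    if spacing <= 0:
        raise ValueError("point spacing must be positive")
    return float(abs(frequency_to_mz(model, center_freq - spacing)
                     - frequency_to_mz(model, center_freq)))


def mark_high_fsd(peaks, min_peaks: int = 4) -> float | None:
    """Flag peaks whose FSD exceeds median + 1.5 * IQR of the FSD
    distribution over peaks observed in >= 2 scans (marked, never removed).

    Returns the threshold, or None when fewer than ``min_peaks`` eligible
    peaks exist (no flagging attempted).
    """
    eligible = [p for p in peaks if p.n_scans >= 2]
    if len(eligible) < min_peaks:
        return None
    fsd = np.array([p.center_freq_sd for p in eligible])
    q1, q3 = np.percentile(fsd, [25, 75])
    thr = float(np.median(fsd) + 1.5 * (q3 - q1))
    for p in eligible:
        if p.center_freq_sd > thr:
            p.flags["high_fsd"] = True
    return thr


def _censored_normal_mean(x: np.ndarray, sigma: float, n_censored: int,
                          censor_point: float) -> float:
    """MLE of mu for a left-censored normal with known sigma: observed
    values ``x`` plus ``n_censored`` observations known only to lie below
    ``censor_point``."""
    if sigma <= 0 or n_censored <= 0:
        return float(x.mean())

    def nll(mu):
        ll = np.sum(norm.logpdf(x, mu, sigma))
        ll += n_censored * norm.logcdf((censor_point - mu) / sigma)
        return -ll

    span = 6.0 * sigma + 1.0
    res = minimize_scalar(nll, bounds=(x.mean() - span, x.mean() + span),
                          method="bounded")
    return float(res.x)


def correct_height_sd(peaks, n_total_scans: int, rng=None,
                      min_calibration_peaks: int = 20,
                      fractions=None, n_draws: int = 200):
    """Experimental censoring correction of height mean/SD (natural-log
    space calibration).

    Peaks present in ALL scans calibrate the shrinkage: for each fraction f
    in 5%..95% (step 5%), ``n_draws`` random scan subsets of size round(f*S)
    give the mean ratio of subset log-SD to full log-SD; a cubic polynomial
    of ratio against fraction predicts the shrinkage at each peak's scan
    fraction.  Corrected log-SD = observed log-SD / predicted ratio;
    corrected mean = exp of the left-censored-normal MLE of the mean log
    height, censoring at the peak's minimum observed normalized log height.

    With fewer than ``min_calibration_peaks`` all-scan peaks the correction
    is skipped (fields stay None) with a warning.  Returns the fitted
    polynomial coefficients (numpy polyfit order) or None.
    """
    rng = np.random.default_rng(rng)
    if fractions is None:
        fractions = np.arange(0.05, 0.951, 0.05)
    calib = [p for p in peaks if p.n_scans == n_total_scans
             and n_total_scans >= 3]
    if len(calib) < min_calibration_peaks:
        log.warning("censoring correction skipped: %d all-scan peaks "
                    "(< %d)", len(calib), min_calibration_peaks)
        return None
    H = np.array([[p.scan_log_heights[s] for s in sorted(p.scan_log_heights)]
                  for p in calib])
    full_sd = H.std(axis=1, ddof=1)
    ok = full_sd > 0
    H, full_sd = H[ok], full_sd[ok]
    if H.shape[0] < min_calibration_peaks:
        log.warning("censoring correction skipped: degenerate calibration")
        return None
    S = n_total_scans
    mean_ratios = []
    for f in fractions:
        k = max(2, int(round(f * S)))
        ratios = np.empty(n_draws)
        for d in range(n_draws):
            idx = rng.choice(S, size=k, replace=False)
            ratios[d] = np.mean(H[:, idx].std(axis=1, ddof=1) / full_sd)
        mean_ratios.append(ratios.mean())
    coefs = np.polyfit(np.asarray(fractions), np.asarray(mean_ratios), 3)
    poly = np.poly1d(coefs)
    for p in peaks:
        if p.n_scans < 2:
            continue
        vals = np.array(sorted(p.scan_log_heights.values()))
        obs_sd = np.array(list(p.scan_log_heights.values())).std(ddof=1)
        frac = min(max(p.scan_fraction, float(fractions[0])), 1.0)
        ratio = float(poly(min(frac, float(fractions[-1])))) \
            if frac < 1.0 else 1.0
        ratio = max(ratio, 1e-3)
        corr_sd = float(obs_sd / ratio)
        n_cens = n_total_scans - p.n_scans
        mu = _censored_normal_mean(vals, corr_sd, n_cens, float(vals.min()))
        p.height_sd_corrected = corr_sd
        p.height_mean_corrected = float(np.exp(mu))
    return coefs
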