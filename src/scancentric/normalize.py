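"""Scan-to-scan intensity normalization.

Scans of a direct-infusion acquisition are near-replicates whose overall
intensity differs multiplicatively (trap fill, spray stability).  Each scan
is normalized to a single reference scan by the median difference of
natural-log peak heights over a qualifying peak subset:

* presence filter — peaks present in at least as many scans as the 95th
  percentile of per-peak scan counts;
* intensity filter — peaks whose log height is at least 0.7 of the maximum
  log peak height in the scan (applied per scan; the ratio is log-base
  invariant).  Restricting to the most intense peaks avoids the
  intensity-correlated component of scan-to-scan differences.

The reference scan minimizes the summed Euclidean distance between log
height vectors over shared peaks.  A two-pass variant re-derives the
factors after excluding peaks whose normalized log height has absolute
Pearson correlation > 0.5 with scan order (an artifact attributed to a
gradient in the sample well); those peaks are flagged in the final output.

All operations take a peak x scan matrix (pandas DataFrame) of natural-log
heights with NaN for peaks missing from a scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationError",
    "NormalizationResult",
    "select_normalization_peaks",
    "choose_reference_scan",
    "compute_factors",
    "detect_scan_correlated_peaks",
    "two_pass_normalize",
]

log = logging.getLogger(__name__)

MODES = ("nonorm", "singlenorm", "singlenorm_int", "doublenorm")


class NormalizationError(RuntimeError):
    pass


@dataclass
class NormalizationResult:
    reference_scan: object
    factors: "pd.Series"          # per-scan additive ln-intensity offsets
    used_peaks: list = field(default_factory=list)
    scan_correlated_peaks: list = field(default_factory=list)
    pass_count: int = 1
    mode: str = "doublenorm"


def select_normalization_peaks(log_heights: pd.DataFrame,
                               intensity_filter: bool = True,
                               intensity_ratio: float = 0.7,
                               presence_percentile: float = 95.0,
                               min_peaks_per_scan: int = 25) -> pd.DataFrame:
    """Boolean peak x scan usability mask for normalization.

    A (peak, scan) entry is usable when the peak is observed in the scan,
    passes the presence filter, and (optionally) its log height is
    >= intensity_ratio * the scan's maximum log peak height.  Raises
    NormalizationError when any scan retains fewer than
    ``min_peaks_per_scan`` usable peaks.
    """
    obs = log_heights.notna()
    counts = obs.sum(axis=1)
    thresh = np.percentile(counts.to_numpy(), presence_percentile)
    present_ok = counts >= thresh
    mask = obs & present_ok.to_numpy()[:, None]
    if intensity_filter:
        scan_max = log_heights.max(axis=0)
        ok = log_heights.ge(intensity_ratio * scan_max, axis=1)
        mask &= ok.fillna(False)
    per_scan = mask.sum(axis=0)
    low = per_scan[per_scan < min_peaks_per_scan]
    if len(low):
        raise NormalizationError(
            "scans with fewer than "
            f"{min_peaks_per_scan} qualifying normalization peaks: "
            f"{dict(low)}")
    return mask


def choose_reference_scan(log_heights: pd.DataFrame,
                          mask: pd.DataFrame | None = None):
    """Scan with the lowest summed Euclidean distance of log heights to all
    other scans, over the peaks shared (and usable) in both scans.

    Scans sharing no peaks with any other scan are excluded from candidacy
    with a warning.  Ties break to the earliest scan (column order).
    """
    if mask is None:
        mask = log_heights.notna()
    if log_heights.shape[1] < 2:
        raise NormalizationError("need at least 2 scans with shared peaks")
    H = log_heights.to_numpy()
    M = mask.to_numpy()
    S = H.shape[1]
    totals = np.zeros(S)
    any_shared = np.zeros(S, dtype=bool)
    for i in range(S):
        for j in range(i + 1, S):
            shared = M[:, i] & M[:, j]
            if not shared.any():
                continue
            d = float(np.sqrt(np.sum((H[shared, i] - H[shared, j]) ** 2)))
            totals[i] += d
            totals[j] += d
            any_shared[i] = any_shared[j] = True
    if not any_shared.any():
        raise NormalizationError("no pair of scans shares a peak")
    for k in np.nonzero(~any_shared)[0]:
        log.warning("scan %s shares no peaks with any other scan; "
                    "excluded from reference candidacy",
                    log_heights.columns[k])
    totals[~any_shared] = np.inf
    return log_heights.columns[int(np.argmin(totals))]


def compute_factors(log_heights: pd.DataFrame, reference,
                    mask: pd.DataFrame | None = None) -> pd.Series:
    """Per-scan offsets: median over shared usable peaks of
    (ln h in scan i - ln h in reference).  Scans sharing no usable peak with
    the reference get NaN (dropped downstream) with a warning."""
    if mask is None:
        mask = log_heights.notna()
    ref_ok = mask[reference]
    factors = {}
    for col in log_heights.columns:
        shared = mask[col] & ref_ok
        if not shared.any():
            log.warning("scan %s shares no peaks with reference %s; dropped",
                        col, reference)
            factors[col] = np.nan
            continue
        diff = log_heights.loc[shared, col] - log_heights.loc[shared,
                                                              reference]
        factors[col] = float(diff.median())
    return pd.Series(factors)


def detect_scan_correlated_peaks(log_heights: pd.DataFrame, order=None,
                                 threshold: float = 0.5) -> list:
    """Peaks whose (normalized) log height has |Pearson r| > threshold with
    scan order.  Peaks observed in fewer than 3 scans, or with zero
    variance, are never flagged."""
    if order is None:
        order = np.arange(log_heights.shape[1], dtype=float)
    order = np.asarray(order, dtype=float)
    flagged = []
    H = log_heights.to_numpy()
    for k, pid in enumerate(log_heights.index):
        row = H[k]
        ok = ~np.isnan(row)
        if ok.sum() < 3:
            continue
        y = row[ok]
        x = order[ok]
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if np.isfinite(r) and abs(r) > threshold:
            flagged.append(pid)
    return flagged


def two_pass_normalize(log_heights: pd.DataFrame, mode: str = "doublenorm",
                       intensity_ratio: float = 0.7,
                       presence_percentile: float = 95.0,
                       min_peaks_per_scan: int = 25,
                       corr_threshold: float = 0.5,
                       order=None) -> NormalizationResult:
    """Scan normalization in one of the processing modes.

    nonorm          identity (all factors 0);
    singlenorm      single pass, presence-filtered peaks only;
    singlenorm_int  single pass, presence + intensity filtered peaks;
    doublenorm      two passes, excluding scan-order-correlated peaks in the
                    second.
    """
    if mode not in MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    cols = list(log_heights.columns)
    if mode == "nonorm":
        return NormalizationResult(
            reference_scan=cols[0] if cols else None,
            factors=pd.Series(0.0, index=cols),
            used_peaks=[], scan_correlated_peaks=[], pass_count=1,
            mode=mode)
    mask = select_normalization_peaks(
        log_heights,
        intensity_filter=(mode != "singlenorm"),
        intensity_ratio=intensity_ratio,
        presence_percentile=presence_percentile,
        min_peaks_per_scan=min_peaks_per_scan)
    ref = choose_reference_scan(log_heights, mask)
    factors = compute_factors(log_heights, ref, mask)
    used = list(log_heights.index[mask.any(axis=1)])
    correlated = []
    pass_count = 1
    if mode == "doublenorm":
        normalized = log_heights.sub(factors, axis=1)
        correlated = detect_scan_correlated_peaks(
            normalized, order=order, threshold=corr_threshold)
        mask2 = mask.copy()
        if correlated:
            mask2.loc[correlated, :] = False
        per_scan = mask2.sum(axis=0)
        if (per_scan >= 1).all() and mask2.to_numpy().any():
            factors = compute_factors(log_heights, ref, mask2)
            used = list(log_heights.index[mask2.any(axis=1)])
        else:
            log.warning("second normalization pass left empty scans; "
                        "keeping first-pass factors")
        pass_count = 2
    factors = factors.dropna()
    return NormalizationResult(reference_scan=ref, factors=factors,
                               used_peaks=used,
                               scan_correlated_peaks=correlated,
                               pass_count=pass_count, mode=mode)
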