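"""Post-hoc quality metrics for characterized peaks.

Covers the relative standard deviation (RSD = across-scan SD / mean of raw
heights) and its distribution modes, natural-abundance-probability (NAP)
log-ratio consistency, ppm-window peak matching against external centroid
lists, and high-peak-density (HPD) site detection on centroid lists in
frequency space.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .centroid import find_bumps

__all__ = ["RsdSummary", "NapPairDiff", "HpdSite", "compute_rsd",
           "rsd_modes", "nap_ratio_diffs", "match_peaks_ppm",
           "detect_hpd_sites"]


@dataclass
class RsdSummary:
    per_peak: "pd.DataFrame"      # peak_id, rsd, n_scans
    mean: float
    sd: float
    median: float
    max: float
    modes: list = field(default_factory=list)


def compute_rsd(scan_heights: dict, min_scans: int = 3,
                with_modes: bool = True) -> RsdSummary:
    """RSD per peak from raw-space scan-level heights.

    ``scan_heights`` maps peak_id -> sequence of raw heights across the
    scans the peak was observed in; only peaks with >= ``min_scans``
    observations enter the distribution (sample SD, n-1).
    """
    rows = []
    for pid, h in scan_heights.items():
        h = np.asarray(h, dtype=float)
        if h.size < min_scans:
            continue
        m = h.mean()
        rows.append((pid, float(h.std(ddof=1) / m), int(h.size)))
    df = pd.DataFrame(rows, columns=["peak_id", "rsd", "n_scans"])
    if df.empty:
        return RsdSummary(per_peak=df, mean=float("nan"), sd=float("nan"),
                          median=float("nan"), max=float("nan"), modes=[])
    r = df["rsd"].to_numpy()
    modes = rsd_modes(r) if (with_modes and r.size >= 10) else []
    return RsdSummary(per_peak=df, mean=float(r.mean()),
                      sd=float(r.std(ddof=1)) if r.size > 1 else 0.0,
                      median=float(np.median(r)), max=float(r.max()),
                      modes=modes)


def rsd_modes(values, rel_height: float = 0.2, grid_size: int = 512) -> list:
    """Up to two mode locations of a distribution, low to high.

    Gaussian kernel density with Silverman bandwidth, local maxima by
    bump-hunting on the density curve; the second mode is reported only if
    its density is >= ``rel_height`` x the tallest.  A degenerate (all
    equal) sample yields the single shared value.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return []
    if np.ptp(v) == 0:
        return [float(v[0])]
    kde = gaussian_kde(v, bw_method="silverman")
    pad = 3.0 * v.std() * kde.factor
    grid = np.linspace(v.min() - pad, v.max() + pad, grid_size)
    dens = kde(grid)
    cand = []
    for s, e in find_bumps(dens):
        k = s + int(np.argmax(dens[s:e + 1]))
        cand.append((float(dens[k]), float(grid[k])))
    if not cand:
        cand = [(float(dens.max()), float(grid[int(np.argmax(dens))]))]
    cand.sort(reverse=True)
    modes = [cand[0][1]]
    if len(cand) > 1 and cand[1][0] >= rel_height * cand[0][0]:
        modes.append(cand[1][1])
    return sorted(modes)


@dataclass
class NapPairDiff:
    peak_1: object
    peak_2: object
    nap_log_ratio: float
    int_log_ratio: float
    abs_diff: float


def nap_ratio_diffs(peak_group) -> list:
    """Pairwise |ln(NAP1/NAP2) - ln(I1/I2)| over a peak group.

    ``peak_group`` maps peak_id -> (height, NAP); the two log-ratios should
    agree when relative intensities track natural abundance.  Pairs with a
    non-positive height or NAP are skipped with a warning.
    """
    items = list(peak_group.items())
    out = []
    for (id1, (h1, n1)), (id2, (h2, n2)) in itertools.combinations(items, 2):
        if min(h1, h2) <= 0 or min(n1, n2) <= 0:
            warnings.warn(f"skipping pair ({id1}, {id2}): non-positive "
                          "height or NAP")
            continue
        nap_lr = float(np.log(n1 / n2))
        int_lr = float(np.log(h1 / h2))
        out.append(NapPairDiff(peak_1=id1, peak_2=id2, nap_log_ratio=nap_lr,
                               int_log_ratio=int_lr,
                               abs_diff=abs(nap_lr - int_lr)))
    return out


def match_peaks_ppm(reference_mz, query_mz, ppm: float = 2.0) -> list:
    """For each reference m/z, the nearest query m/z within +/- ppm.

    Returns a list aligned with ``reference_mz`` of query indices or None.
    One-to-one matching is NOT enforced: a query centroid may match several
    reference peaks.  Equidistant candidates resolve to the lower m/z.
    """
    ref = np.asarray(reference_mz, dtype=float)
    qry = np.asarray(query_mz, dtype=float)
    order = np.argsort(qry, kind="stable")
    qs = qry[order]
    out = []
    for mz in ref:
        tol = mz * ppm * 1e-6
        lo = np.searchsorted(qs, mz - tol, side="left")
        hi = np.searchsorted(qs, mz + tol, side="right")
        if lo >= hi:
            out.append(None)
            continue
        cand = qs[lo:hi]
        d = np.abs(cand - mz)
        best = np.nonzero(d == d.min())[0][0]  # tie -> lower m/z
        out.append(int(order[lo + best]))
    return out


@dataclass
class HpdSite:
    window: tuple                 # (start_freq, end_freq)
    peak_count: int
    flagged: bool = True


def detect_hpd_sites(centroid_freqs, window_width: float = 1000.0,
                     stride: float = 100.0) -> list:
    """High-peak-density sites among centroids in frequency space.

    Sliding windows ``window_width`` frequency units wide with the given
    stride count centroids; windows whose count exceeds
    median + 1.5 * IQR of the non-zero window counts are flagged, and
    overlapping flagged windows are merged into sites.
    """
    f = np.sort(np.asarray(centroid_freqs, dtype=float))
    if f.size == 0:
        return []
    starts = np.arange(f[0], f[-1] + stride, stride)
    ends = starts + window_width
    counts = (np.searchsorted(f, ends, side="right")
              - np.searchsorted(f, starts, side="left"))
    nz = counts[counts > 0]
    if nz.size == 0:
        return []
    q1, q3 = np.percentile(nz, [25, 75])
    thr = np.median(nz) + 1.5 * (q3 - q1)
    flagged = counts > thr
    sites = []
    i = 0
    while i < len(starts):
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(starts) and flagged[j + 1] \
                and starts[j + 1] <= ends[j]:
            j += 1
        lo, hi = float(starts[i]), float(ends[j])
        n = int(np.searchsorted(f, hi, side="right")
                - np.searchsorted(f, lo, side="left"))
        sites.append(HpdSite(window=(lo, hi), peak_count=n))
        i = j + 1
    return sites
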