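"""Scan-level peak detection and weighted parabolic centroiding.

A profile peak that is Gaussian in frequency is exactly parabolic in
log-intensity, so each candidate bump is centroided by a weighted quadratic
fit of ln(intensity + c) against position:

    ln(I + c) = a + x*p + y*p^2,   y < 0

with per-point weights equal to the shifted log-intensity relative to the
maximum shifted log-intensity of the bump.  The vertex -x/(2y) is the
centroided center, a - x^2/(4y) the log-height, and the integral of
exp(fit) over the point support the peak area.  The additive constant c
(default 1, negligible against typical intensities >= 1e3) makes the log
defined at the instrument's zero-floored baseline points.

Candidate bumps require two strictly increasing points before and two
strictly decreasing points after a local maximum; plateaus break a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = ["ScanPeak", "find_bumps", "fit_weighted_parabola",
           "characterize_region_scans"]


@dataclass
class ScanPeak:
    """A single-scan centroid."""

    scan_id: object
    center_freq: float
    center_mz: float
    log_height: float
    height: float
    area: float
    ssr: float
    n_points: int
    region_id: object = None
    # fitted quadratic in original position coordinates is recoverable from
    # (vertex, log_height, curvature); curvature kept for aggregation checks
    curvature: float = float("nan")
    support: tuple = ()  # (pos_min, pos_max) of the fitted points


def find_bumps(intensity) -> list:
    """Maximal candidate bump index ranges [start, end] (inclusive).

    A candidate contains a local maximum at index m with
    I[m-2] < I[m-1] < I[m] > I[m+1] > I[m+2] (strict); the returned window
    is the maximal strictly increasing run into m plus the maximal strictly
    decreasing run out of m.
    """
    I = np.asarray(intensity, dtype=float)
    n = I.size
    out = []
    m = 2
    while m < n - 2:
        if (I[m - 2] < I[m - 1] < I[m] and I[m] > I[m + 1] > I[m + 2]):
            s = m
            while s > 0 and I[s - 1] < I[s]:
                s -= 1
            e = m
            while e < n - 1 and I[e + 1] < I[e]:
                e += 1
            out.append((s, e))
            m = e + 1
        else:
            m += 1
    return out


def fit_weighted_parabola(pos, intensity, c: float = 1.0):
    """Weighted quadratic fit of ln(I + c) to position.

    Returns a dict with vertex position, log_height, height, area, weighted
    SSR, curvature and n_points, or None when the candidate is rejected
    (no concavity, i.e. fitted y >= 0, or a degenerate design).
    """
    p = np.asarray(pos, dtype=float)
    I = np.asarray(intensity, dtype=float)
    if p.size < 4 or np.unique(p).size < 3:
        return None
    logI = np.log(I + c)
    mx = logI.max()
    if mx <= 0:
        return None
    w = logI / mx
    w = np.clip(w, 0.0, None)
    # center the position axis for conditioning; map coefficients back after
    p0 = p.mean()
    q = p - p0
    X = np.column_stack([np.ones_like(q), q, q * q])
    sw = np.sqrt(w)
    try:
        coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], logI * sw,
                                           rcond=None)
    except np.linalg.LinAlgError:
        return None
    if rank < 3:
        return None
    a_c, x_c, y_c = coef
    if y_c >= 0:
        return None
    vertex = p0 - x_c / (2.0 * y_c)
    log_height = a_c - x_c * x_c / (4.0 * y_c)
    resid = logI - X @ coef
    ssr = float(np.sum(w * resid * resid))
    # area = integral of exp(fit) over the point support
    s = np.sqrt(-y_c)
    lo, hi = p.min(), p.max()
    area = (np.exp(log_height) * np.sqrt(np.pi) / (2.0 * s)
            * (erf(s * (hi - vertex)) - erf(s * (lo - vertex))))
    return {
        "center": float(vertex),
        "log_height": float(log_height),
        "height": float(np.exp(log_height)),
        "area": float(area),
        "ssr": ssr,
        "curvature": float(y_c),
        "n_points": int(p.size),
        "support": (float(lo), float(hi)),
    }


def characterize_region_scans(region_id, scan_points, inverse_mz=None,
                              c: float = 1.0):
    """Centroid one peak region across scans.

    ``scan_points`` maps scan_id -> (freq positions ascending, intensities)
    restricted to the region.  Per scan, bump candidates are detected and
    fitted; a scan contributing two or more accepted peaks is discarded for
    this region entirely (its data are suspect), a scan with none (peak
    floored out) contributes nothing.

    Returns (scan_peaks, discarded_scan_ids).  ``inverse_mz`` is an optional
    callable converting a frequency to m/z for the ScanPeak record.
    """
    peaks = []
    discarded = []
    for scan_id, (pos, inten) in scan_points.items():
        accepted = []
        for s, e in find_bumps(inten):
            fit = fit_weighted_parabola(pos[s:e + 1], inten[s:e + 1], c=c)
            if fit is not None:
                accepted.append(fit)
        if len(accepted) >= 2:
            discarded.append(scan_id)
            continue
        if not accepted:
            continue
        fit = accepted[0]
        peaks.append(ScanPeak(
            scan_id=scan_id,
            center_freq=fit["center"],
            center_mz=(float(inverse_mz(fit["center"]))
                       if inverse_mz is not None else float("nan")),
            log_height=fit["log_height"],
            height=fit["height"],
            area=fit["area"],
            ssr=fit["ssr"],
            n_points=fit["n_points"],
            region_id=region_id,
            curvature=fit["curvature"],
            support=fit["support"],
        ))
    return peaks, discarded
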