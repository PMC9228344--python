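"""m/z <-> spectral-frequency conversion for Orbitrap profile scans.

Orbitrap ion axial frequency scales as 1/sqrt(m/z), and the raw files expose
only the m/z grid.  A proxy frequency is recovered per point as the midpoint
m/z of two adjacent grid points divided by their spacing; on a Fusion-like
grid (adjacent frequency difference 0.5) this proxy equals the axial
frequency.  A per-scan regression of frequency on
[1, 1/mz, 1/sqrt(mz), 1/cbrt(mz)] (forward model) and of m/z on
[1, 1/f, 1/f^2, 1/f^3] (inverse model) is fitted on the "useful" points whose
local frequency difference lies within a relative tolerance of the modal
difference.  A single master model (the scan whose sqrt-term coefficient is
closest to the across-scan median) converts all scans, which preserves the
m/z point ordering; per-scan models do not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyModel",
    "FrequencyDiffSummary",
    "ProxyFrequency",
    "ScanFitError",
    "derive_proxy_frequency",
    "summarize_frequency_diffs",
    "fit_frequency_model",
    "fit_mz_frequency",
    "select_master_model",
    "detect_outlier_scans",
    "mz_to_frequency",
    "frequency_to_mz",
    "check_order_preservation",
]

log = logging.getLogger(__name__)


class ScanFitError(ValueError):
    """A scan could not support a frequency-model fit."""


@dataclass
class FrequencyModel:
    """Forward (m/z -> frequency) and inverse (frequency -> m/z) fits.

    Forward: f = a + x/mz + y/sqrt(mz) + z/cbrt(mz)
    Inverse: mz = inv_a + inv_x/f + inv_y/f**2 + inv_z/f**3
    """

    a: float
    x: float
    y: float
    z: float
    inv_a: float
    inv_x: float
    inv_y: float
    inv_z: float
    r2: float = float("nan")
    source_scan: object = None

    def to_dict(self) -> dict:
        return {
            "a": self.a, "x": self.x, "y": self.y, "z": self.z,
            "inv_a": self.inv_a, "inv_x": self.inv_x,
            "inv_y": self.inv_y, "inv_z": self.inv_z,
            "r2": self.r2, "source_scan": self.source_scan,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencyModel":
        return cls(**d)

    @classmethod
    def sqrt_model(cls, y: float, source_scan=None) -> "FrequencyModel":
        """Pure-physics model f = y/sqrt(mz), exactly invertible
        (mz = y^2/f^2, i.e. inv_y = y^2)."""
        return cls(a=0.0, x=0.0, y=y, z=0.0,
                   inv_a=0.0, inv_x=0.0, inv_y=y * y, inv_z=0.0,
                   r2=1.0, source_scan=source_scan)


@dataclass
class FrequencyDiffSummary:
    """Mode/median of adjacent-point frequency differences and the accepted
    band mode*(1 -/+ tol) used to gate model-usable points."""

    mode_diff: float
    median_diff: float
    lo: float
    hi: float
    n_useful: int


@dataclass
class ProxyFrequency:
    """Per-adjacent-pair proxy frequency triples for one scan.

    ``mid_mz``/``freq`` have length n-1 for an n-point scan; ``diff`` holds
    the absolute successive differences of ``freq`` (length n-2), aligned so
    ``diff[i]`` is the difference between ``freq[i+1]`` and ``freq[i]``.
    """

    mid_mz: np.ndarray
    freq: np.ndarray
    diff: np.ndarray
    n_dropped_pairs: int = 0


def derive_proxy_frequency(scan) -> ProxyFrequency:
    """Proxy frequency per adjacent m/z pair: mid = (mz_i + mz_{i+1})/2,
    freq = mid / (mz_{i+1} - mz_i).

    Pairs with zero m/z spacing (duplicate values) are dropped with a warning.
    """
    mz = np.asarray(scan.mz, dtype=float)
    if mz.size < 2:
        raise ScanFitError("need at least 2 points to derive proxy frequency")
    dmz = np.diff(mz)
    keep = dmz > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} duplicate-m/z pairs in scan "
                      f"{getattr(scan, 'scan_id', '?')}")
    mid = 0.5 * (mz[:-1] + mz[1:])[keep]
    freq = mid / dmz[keep]
    diff = np.abs(np.diff(freq))
    return ProxyFrequency(mid_mz=mid, freq=freq, diff=diff,
                          n_dropped_pairs=n_dropped)


def summarize_frequency_diffs(diffs, tol: float = 0.02) -> FrequencyDiffSummary:
    """Modal and median adjacent-point frequency difference.

    The mode is the midpoint of the maximum-count histogram bin with bin
    width median/100; bins are anchored at ``min - width/2`` so a constant
    difference list yields the constant itself. ``lo``/``hi`` bound the
    accepted band at mode*(1 - tol) and mode*(1 + tol).
    """
    d = np.abs(np.asarray(diffs, dtype=float))
    if d.size == 0:
        raise ValueError("empty frequency-difference list")
    median = float(np.median(d))
    if d.size == 1 or np.ptp(d) == 0 or median == 0:
        mode = float(d[0]) if np.ptp(d) == 0 else median
    else:
        width = median / 100.0
        edges = np.arange(d.min() - width / 2.0, d.max() + width, width)
        counts, edges = np.histogram(d, bins=edges)
        k = int(np.argmax(counts))
        mode = float(0.5 * (edges[k] + edges[k + 1]))
    lo = mode * (1.0 - tol)
    hi = mode * (1.0 + tol)
    n_useful = int(np.count_nonzero((d >= lo) & (d <= hi)))
    return FrequencyDiffSummary(mode_diff=mode, median_diff=median,
                                lo=lo, hi=hi, n_useful=n_useful)


def _forward_design(mz: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(mz), 1.0 / mz,
                            mz ** -0.5, mz ** (-1.0 / 3.0)])


def _inverse_design(f: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(f), 1.0 / f, f ** -2.0, f ** -3.0])


def fit_mz_frequency(mz, freq, source_scan=None) -> FrequencyModel:
    """OLS fit of the forward and inverse models on paired (m/z, frequency)
    observations; r2 is that of the forward fit."""
    mz = np.asarray(mz, dtype=float)
    freq = np.asarray(freq, dtype=float)
    if mz.size != freq.size:
        raise ValueError("mz and freq must have equal length")
    if np.unique(mz).size < 4:
        raise ScanFitError(
            f"rank-deficient design: {np.unique(mz).size} distinct m/z "
            "values, need >= 4")
    X = _forward_design(mz)
    coef, _, rank, _ = np.linalg.lstsq(X, freq, rcond=None)
    if rank < 4:
        raise ScanFitError("rank-deficient forward design")
    pred = X @ coef
    ss_res = float(np.sum((freq - pred) ** 2))
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # fit the inverse model in the scaled variable u = f0/f: the raw
    # columns 1/f, 1/f^2, 1/f^3 span ~18 orders of magnitude at Orbitrap
    # frequencies and would fall below lstsq's rank cutoff
    f0 = float(np.median(freq))
    u = f0 / freq
    Xi = np.column_stack([np.ones_like(u), u, u * u, u ** 3])
    b, _, inv_rank, _ = np.linalg.lstsq(Xi, mz, rcond=None)
    if inv_rank < 4:
        # degenerate frequency support (e.g. constant): keep the forward
        # fit, accept lstsq's minimal-norm inverse solution
        log.warning("inverse frequency design rank-deficient (rank %d)",
                    inv_rank)
    inv_coef = np.array([b[0], b[1] * f0, b[2] * f0 ** 2, b[3] * f0 ** 3])
    return FrequencyModel(a=float(coef[0]), x=float(coef[1]),
                          y=float(coef[2]), z=float(coef[3]),
                          inv_a=float(inv_coef[0]), inv_x=float(inv_coef[1]),
                          inv_y=float(inv_coef[2]), inv_z=float(inv_coef[3]),
                          r2=min(max(r2, 0.0), 1.0), source_scan=source_scan)


def fit_frequency_model(scan, summary: FrequencyDiffSummary | None = None,
                        tol: float = 0.02,
                        min_useful: int = 10) -> FrequencyModel:
    """Fit the per-scan frequency model on the scan's useful proxy points.

    A proxy point is useful when its local frequency difference (to the next
    proxy point) lies inside [summary.lo, summary.hi].  Requires at least
    ``min_useful`` such points (4 coefficients need comfortable
    overdetermination).
    """
    proxy = derive_proxy_frequency(scan)
    if summary is None:
        summary = summarize_frequency_diffs(proxy.diff, tol=tol)
    useful = (proxy.diff >= summary.lo) & (proxy.diff <= summary.hi)
    mz_u = proxy.mid_mz[:-1][useful]
    f_u = proxy.freq[:-1][useful]
    if mz_u.size < min_useful:
        raise ScanFitError(
            f"scan {getattr(scan, 'scan_id', '?')}: only {mz_u.size} useful "
            f"points (< {min_useful})")
    return fit_mz_frequency(mz_u, f_u,
                            source_scan=getattr(scan, "scan_id", None))


def select_master_model(models) -> FrequencyModel:
    """Model of the scan whose sqrt-term coefficient ``y`` is closest to the
    median of ``y`` across scans; ties broken by earliest scan."""
    models = list(models)
    if not models:
        raise ValueError("no scan models to select from")
    ys = np.array([m.y for m in models])
    med = np.median(ys)
    return models[int(np.argmin(np.abs(ys - med)))]


def detect_outlier_scans(models) -> list:
    """Scan ids whose sqrt-term coefficient falls outside the Tukey fences
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the across-scan distribution.

    With fewer than 4 scans no flagging is attempted (quartiles are
    meaningless) and a warning is logged.
    """
    models = list(models)
    if len(models) < 4:
        log.warning("only %d scan models; skipping outlier detection",
                    len(models))
        return []
    ys = np.array([m.y for m in models])
    q1, q3 = np.percentile(ys, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [m.source_scan for m, y in zip(models, ys) if y < lo or y > hi]


def mz_to_frequency(model: FrequencyModel, mz):
    """Forward conversion a + x/mz + y/sqrt(mz) + z/cbrt(mz); vectorized."""
    arr = np.asarray(mz, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("m/z values must be positive")
    out = model.a + model.x / arr + model.y * arr ** -0.5 \
        + model.z * arr ** (-1.0 / 3.0)
    return out if arr.ndim else float(out)


def frequency_to_mz(model: FrequencyModel, freq):
    """Inverse conversion inv_a + inv_x/f + inv_y/f^2 + inv_z/f^3."""
    arr = np.asarray(freq, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("frequency values must be positive")
    out = model.inv_a + model.inv_x / arr + model.inv_y * arr ** -2.0 \
        + model.inv_z * arr ** -3.0
    return out if arr.ndim else float(out)


@dataclass
class OrderReport:
    ok: bool
    violations: list = field(default_factory=list)  # (scan_id, index)


def check_order_preservation(scans, model: FrequencyModel) -> OrderReport:
    """Verify that converted frequencies are strictly decreasing wherever
    m/z is strictly increasing, for every scan (frequency order must be the
    exact reverse of m/z order)."""
    violations = []
    for scan in scans.scans:
        mz = np.asarray(scan.mz, dtype=float)
        if mz.size < 2:
            continue
        f = mz_to_frequency(model, mz)
        bad = np.nonzero(np.diff(f) >= 0)[0]
        violations.extend((scan.scan_id, int(i)) for i in bad)
    return OrderReport(ok=not violations, violations=violations)
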