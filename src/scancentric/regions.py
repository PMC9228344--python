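"""Integer-interval algebra over frequency space.

Conventions used throughout the package:

* A frequency position maps to the integer ``round(freq * multiplier)`` with
  half-away-from-zero rounding (multiplier 400 by default), which preserves
  the spacing between individual points.
* All intervals are CLOSED on both ends; two intervals overlap iff they
  share at least one integer position.  Merging joins transitively
  overlapping intervals (sharing a position), not merely adjacent ones.
* Sliding windows are ``width_points`` frequency points wide with a stride
  of ``stride_points`` points; tiled windows are the width==stride special
  case.  One "point" is the modal adjacent-point frequency difference
  (0.5 for Fusion-like data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntegerInterval",
    "RegionSet",
    "TileSummary",
    "to_interval",
    "make_windows",
    "count_nonzero_density",
    "tile_percentiles",
    "compute_noise_cutoff",
    "build_initial_regions",
    "merge_intervals",
    "split_region_by_peaks",
]


@dataclass(frozen=True)
class IntegerInterval:
    """Closed integer interval in multiplied-frequency units."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "IntegerInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class RegionSet:
    """Sorted list of integer intervals of one kind.

    ``kind`` is one of sliding | tiled | initial_region | peak_region;
    intervals are pairwise disjoint for every kind except sliding.
    """

    intervals: list
    kind: str = "initial_region"

    def __post_init__(self):
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start)
        if self.kind != "sliding":
            for a, b in zip(self.intervals, self.intervals[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"{self.kind} intervals overlap: {a} / {b}")

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def starts(self) -> np.ndarray:
        return np.array([iv.start for iv in self.intervals], dtype=np.int64)

    def ends(self) -> np.ndarray:
        return np.array([iv.end for iv in self.intervals], dtype=np.int64)


@dataclass
class TileSummary:
    """99th percentile of sliding-window non-zero counts within one tile."""

    tile: IntegerInterval
    p99: float


def to_interval(freq, multiplier: int = 400):
    """Integer position(s) round(freq * multiplier), half away from zero."""
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    arr = np.asarray(freq, dtype=float) * multiplier
    out = (np.sign(arr) * np.floor(np.abs(arr) + 0.5)).astype(np.int64)
    return out if np.ndim(freq) else int(out)


def make_windows(span: IntegerInterval, width_points: int, stride_points: int,
                 point_spacing: float, multiplier: int = 400) -> RegionSet:
    """Sliding (or, when width==stride, tiled) windows covering ``span``.

    Window width is ``width_points * point_spacing * multiplier`` integer
    units; the last window is clipped to the span end.
    """
    if width_points < 1 or stride_points < 1:
        raise ValueError("width and stride must be >= 1 point")
    width = int(round(width_points * point_spacing * multiplier))
    stride = int(round(stride_points * point_spacing * multiplier))
    starts = np.arange(span.start, span.end + 1, stride, dtype=np.int64)
    ends = np.minimum(starts + width - 1, span.end)
    kind = "tiled" if width_points == stride_points else "sliding"
    return RegionSet([IntegerInterval(int(s), int(e))
                      for s, e in zip(starts, ends)], kind=kind)


def count_nonzero_density(positions, windows: RegionSet) -> np.ndarray:
    """Per-window count of non-zero-intensity points (by integer position,
    pooled across all scans; ``positions`` may repeat across scans)."""
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    starts = windows.starts()
    ends = windows.ends()
    return (np.searchsorted(pos, ends, side="right")
            - np.searchsorted(pos, starts, side="left"))


def tile_percentiles(windows: RegionSet, counts, span: IntegerInterval,
                     tile_width_freq: float = 1000.0, multiplier: int = 400,
                     percentile: float = 99.0) -> list:
    """Break the sliding-window counts into fixed-width tiles
    (``tile_width_freq`` frequency units) and take the per-tile percentile
    of the counts; a window belongs to the tile containing its start."""
    counts = np.asarray(counts)
    tw = int(round(tile_width_freq * multiplier))
    starts = windows.starts()
    idx = (starts - span.start) // tw
    out = []
    for k in np.unique(idx):
        sel = counts[idx == k]
        tile = IntegerInterval(int(span.start + k * tw),
                               int(min(span.start + (k + 1) * tw - 1,
                                       span.end)))
        out.append(TileSummary(tile=tile, p99=float(np.percentile(sel,
                                                                  percentile))))
    return out


def compute_noise_cutoff(tile_summaries, multiplier: float = 1.5) -> int:
    """ceiling(median(per-tile 99th-percentile counts) * multiplier).

    ``tile_summaries`` may be TileSummary objects or bare numbers.
    """
    vals = [ts.p99 if isinstance(ts, TileSummary) else float(ts)
            for ts in tile_summaries]
    if not vals:
        raise ValueError("need at least one tile summary")
    return int(math.ceil(float(np.median(vals)) * multiplier))


def merge_intervals(intervals, kind: str = "initial_region") -> RegionSet:
    """Merge transitively overlapping closed intervals into maximal disjoint
    ones (adjacency without a shared position does not merge)."""
    ivs = sorted(intervals, key=lambda iv: iv.start)
    merged = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = IntegerInterval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return RegionSet(merged, kind=kind)


def build_initial_regions(windows: RegionSet, counts, cutoff: int) -> RegionSet:
    """Keep sliding windows with count STRICTLY greater than the cutoff and
    merge overlapping survivors into the initial peak regions."""
    counts = np.asarray(counts)
    kept = [iv for iv, c in zip(windows.intervals, counts) if c > cutoff]
    if not kept:
        raise ValueError("no signal regions: every sliding window fell at or "
                         f"below the noise cutoff {cutoff}")
    return merge_intervals(kept, kind="initial_region")


def split_region_by_peaks(region: IntegerInterval, peak_positions,
                          tile_units: int) -> RegionSet:
    """Split an initial region at empty one-point-wide tiles.

    Scan-level peak centers (integer positions inside ``region``) are binned
    into tiles of ``tile_units`` integer units anchored at the region start;
    each maximal run of occupied tiles becomes one peak region.  A region
    with no peaks yields an empty set (the region is removed).
    """
    pos = np.asarray(peak_positions, dtype=np.int64)
    if pos.size == 0:
        return RegionSet([], kind="peak_region")
    if np.any(pos < region.start) or np.any(pos > region.end):
        raise ValueError("peak positions outside region")
    bins = np.unique((pos - region.start) // tile_units)
    out = []
    run_start = bins[0]
    prev = bins[0]
    for b in bins[1:]:
        if b != prev + 1:
            out.append((run_start, prev))
            run_start = b
        prev = b
    out.append((run_start, prev))
    ivs = [IntegerInterval(int(region.start + s * tile_units),
                           int(min(region.start + (e + 1) * tile_units - 1,
                                   region.end)))
           for s, e in out]
    return RegionSet(ivs, kind="peak_region")
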