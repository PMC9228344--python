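"""Pipeline orchestration: configuration, stage sequencing and QC logging.

Stage order (density filtering and normalization vary with the processing
mode): read -> scan filters -> per-scan frequency models -> outlier-scan
removal -> master model + order check -> frequency conversion -> sliding
window density (noise cutoff unless noperc) -> initial regions -> per-scan
peak detection -> region splitting -> per-region scan peaks with the
multi-peak discard rule -> scan normalization -> cross-scan aggregation ->
(FSD marking in filtersd mode) -> output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import centroid, characterize, frequency, normalize, qc_metrics, regions
from .scan_io import ScanSet, filter_scans, read_profile_mzml, \
    write_characterized_peaks

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run"]

log = logging.getLogger(__name__)

MODES = ("noperc_nonorm", "perc99_nonorm", "singlenorm", "singlenorm_int",
         "doublenorm", "filtersd")

_NORM_MODE = {"noperc_nonorm": "nonorm", "perc99_nonorm": "nonorm",
              "singlenorm": "singlenorm", "singlenorm_int": "singlenorm_int",
              "doublenorm": "doublenorm", "filtersd": "doublenorm"}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline tunables.  Defaults are the method's published operating
    point (4 s scan gap, 2% frequency-difference tolerance, multiplier 400,
    10-point sliding windows with stride 1, 1000-frequency-unit tiles, 99th
    percentile, x1.5 cutoff, 0.7 intensity ratio, 0.5 scan-order
    correlation, 25-peak normalization guard, 2 ppm matching, 3-scan RSD
    minimum)."""

    min_gap_s: float = 4.0
    max_rt_s: float | None = None
    freq_diff_tol: float = 0.02
    interval_multiplier: int = 400
    sliding_width_points: int = 10
    sliding_stride_points: int = 1
    tile_width_freq: float = 1000.0
    density_percentile: float = 99.0
    cutoff_multiplier: float = 1.5
    intensity_ratio_threshold: float = 0.7
    presence_percentile: float = 95.0
    scan_corr_threshold: float = 0.5
    min_norm_peaks: int = 25
    ppm_tolerance: float = 2.0
    min_scans_rsd: int = 3
    mode: str = "filtersd"
    seed: int = 0
    log_constant: float = 1.0
    min_useful_points: int = 10
    mode_diff_consistency_tol: float = 0.10
    min_r2: float = 0.98
    apply_height_correction: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; "
                             f"choose from {MODES}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    peaks: list
    normalization: "normalize.NormalizationResult"
    master_model: "frequency.FrequencyModel"
    point_spacing: float
    median_useful_diff: float
    noise_cutoff: int
    n_initial_regions: int
    scan_table: "pd.DataFrame"      # per retained scan: rt, y, r2, factor
    removed_scans: dict             # scan_id -> reason
    stage_log: list
    config: PipelineConfig
    sample_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.peaks:
            d = p.to_dict()
            flags = d.pop("flags")
            d.update(flags)
            rows.append(d)
        return pd.DataFrame(rows)

    def rsd_summary(self, exclude_high_fsd: bool | None = None,
                    min_scans: int | None = None):
        """RSD distribution over raw-space normalized scan-level heights.

        In filtersd mode high-FSD-flagged peaks are excluded by default
        (they are marked as suspect artifacts)."""
        if exclude_high_fsd is None:
            exclude_high_fsd = self.config.mode == "filtersd"
        if min_scans is None:
            min_scans = self.config.min_scans_rsd
        heights = {}
        for p in self.peaks:
            if exclude_high_fsd and p.flags.get("high_fsd"):
                continue
            heights[p.peak_id] = np.exp(
                np.array(list(p.scan_log_heights.values())))
        return qc_metrics.compute_rsd(heights, min_scans=min_scans)

    def metadata(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "mode": self.config.mode,
            "config": self.config.to_dict(),
            "frequency_model": self.master_model.to_dict(),
            "point_spacing": self.point_spacing,
            "noise_cutoff": self.noise_cutoff,
            "n_initial_regions": self.n_initial_regions,
            "normalization_factors":
                {str(k): float(v)
                 for k, v in self.normalization.factors.items()},
            "reference_scan": str(self.normalization.reference_scan),
            "scan_qc": self.scan_table.to_dict(orient="records"),
            "removed_scans": {str(k): v
                              for k, v in self.removed_scans.items()},
            "stage_log": self.stage_log,
        }

    def write(self, json_path, csv_path=None) -> None:
        write_characterized_peaks(self.peaks, self.metadata(), json_path,
                                  csv_path)


def _stage(stage_log, name, **counts):
    stage_log.append({"stage": name, **counts})
    log.info("stage %s: %s", name, counts)


def run(config: PipelineConfig, source) -> PipelineResult:
    """Run the full characterization on an mzML path or an in-memory
    ScanSet."""
    stage_log = []
    removed = {}
    scanset = source if isinstance(source, ScanSet) \
        else read_profile_mzml(source)
    _stage(stage_log, "read", scans=len(scanset))

    scanset = filter_scans(scanset, config.min_gap_s, config.max_rt_s)
    _stage(stage_log, "scan_filter", scans=len(scanset))

    # per-scan proxy frequency and model fits
    summaries, models, kept = {}, [], []
    for scan in scanset:
        try:
            proxy = frequency.derive_proxy_frequency(scan)
            summ = frequency.summarize_frequency_diffs(
                proxy.diff, tol=config.freq_diff_tol)
            model = frequency.fit_frequency_model(
                scan, summ, min_useful=config.min_useful_points)
        except (frequency.ScanFitError, ValueError) as exc:
            removed[scan.scan_id] = f"model fit failed: {exc}"
            continue
        summaries[scan.scan_id] = (proxy, summ)
        models.append(model)
        kept.append(scan)
    if not models:
        raise PipelineError("no scan yielded a frequency model")
    modes = np.array([summaries[s.scan_id][1].mode_diff for s in kept])
    med_mode = float(np.median(modes))
    off = np.abs(modes - med_mode) / med_mode
    if np.any(off > config.mode_diff_consistency_tol):
        bad = [s.scan_id for s, o in zip(kept, off)
               if o > config.mode_diff_consistency_tol]
        raise PipelineError(
            "modal frequency differences disagree across scans by more "
            f"than {config.mode_diff_consistency_tol:.0%} (mixed "
            f"resolution?): {bad}")
    point_spacing = med_mode

    outliers = set(frequency.detect_outlier_scans(models))
    for sid in outliers:
        removed[sid] = "outlier sqrt-term coefficient"
    models_kept = [m for m in models if m.source_scan not in outliers]
    scans_kept = [s for s in kept if s.scan_id not in outliers]
    _stage(stage_log, "frequency_models", fitted=len(models),
           outlier_scans=len(outliers))

    master = frequency.select_master_model(models_kept)
    order = frequency.check_order_preservation(
        ScanSet(scans=scans_kept, sample_id=scanset.sample_id), master)
    if not order.ok:
        raise PipelineError(
            "master model does not preserve point ordering; first "
            f"violations: {order.violations[:5]}")
    low_r2 = [m.source_scan for m in models_kept if m.r2 < config.min_r2]
    if low_r2:
        log.warning("scans with frequency-fit r2 below %.2f: %s",
                    config.min_r2, low_r2)

    # median point-to-point difference among model-usable points (offsets)
    useful_medians = []
    for s in scans_kept:
        proxy, summ = summaries[s.scan_id]
        d = proxy.diff[(proxy.diff >= summ.lo) & (proxy.diff <= summ.hi)]
        if d.size:
            useful_medians.append(float(np.median(d)))
    median_useful_diff = float(np.median(useful_medians)) \
        if useful_medians else point_spacing

    # conversion: all points of every retained scan via the master model
    mult = config.interval_multiplier
    scan_freq, scan_pos, scan_int = {}, {}, {}
    for s in scans_kept:
        f = frequency.mz_to_frequency(master, s.mz)[::-1]  # ascending
        scan_freq[s.scan_id] = f
        scan_pos[s.scan_id] = regions.to_interval(f, mult)
        scan_int[s.scan_id] = s.intensity[::-1]

    all_pos = np.concatenate([scan_pos[s.scan_id] for s in scans_kept])
    nz_pos = np.concatenate([scan_pos[s.scan_id][scan_int[s.scan_id] > 0]
                             for s in scans_kept])
    if nz_pos.size == 0:
        raise PipelineError("no non-zero intensity points in any scan")
    span = regions.IntegerInterval(int(all_pos.min()), int(all_pos.max()))
    windows = regions.make_windows(span, config.sliding_width_points,
                                   config.sliding_stride_points,
                                   point_spacing, mult)
    counts = regions.count_nonzero_density(nz_pos, windows)
    if config.mode == "noperc_nonorm":
        cutoff = 0
    else:
        tiles = regions.tile_percentiles(
            windows, counts, span, config.tile_width_freq, mult,
            config.density_percentile)
        cutoff = regions.compute_noise_cutoff(tiles,
                                              config.cutoff_multiplier)
    initial = regions.build_initial_regions(windows, counts, cutoff)
    _stage(stage_log, "initial_regions", cutoff=cutoff,
           windows=len(windows), regions=len(initial))

    # per-scan peak detection within initial regions, split, assign
    tile_units = int(round(point_spacing * mult))
    scan_ids = [s.scan_id for s in scans_kept]
    region_peaks = {}      # region_id -> {scan_id: (ScanPeak, slice)}
    region_discards = {}   # region_id -> n multi-peak discarded scans
    region_interval = {}
    rid = 0
    for iv in initial:
        per_scan_fits = {}
        all_centers = []
        for sid in scan_ids:
            pos = scan_pos[sid]
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="right")
            if hi - lo < 5:
                continue
            fpos = scan_freq[sid][lo:hi]
            inten = scan_int[sid][lo:hi]
            fits = []
            for s0, e0 in centroid.find_bumps(inten):
                fit = centroid.fit_weighted_parabola(
                    fpos[s0:e0 + 1], inten[s0:e0 + 1], c=config.log_constant)
                if fit is not None:
                    fits.append((fit, (lo + s0, lo + e0)))
                    all_centers.append(
                        regions.to_interval(fit["center"], mult))
            if fits:
                per_scan_fits[sid] = fits
        if not all_centers:
            continue
        centers = np.asarray(all_centers, dtype=np.int64)
        inside = (centers >= iv.start) & (centers <= iv.end)
        split = regions.split_region_by_peaks(iv, centers[inside],
                                              tile_units)
        for pr in split:
            assigned = {}
            discards = 0
            for sid, fits in per_scan_fits.items():
                here = [(fit, sl) for fit, sl in fits
                        if pr.contains(regions.to_interval(fit["center"],
                                                           mult))]
                if len(here) >= 2:
                    discards += 1
                    continue
                if here:
                    assigned[sid] = here[0]
            if not assigned:
                continue
            region_id = f"R{rid:05d}"
            rid += 1
            region_peaks[region_id] = assigned
            region_discards[region_id] = discards
            region_interval[region_id] = pr
    if not region_peaks:
        raise PipelineError("no peak regions with scan-level peaks")
    _stage(stage_log, "scan_peaks", peak_regions=len(region_peaks))

    # normalization on the ln-height matrix
    logH = pd.DataFrame(
        {sid: {reg: fits[sid][0]["log_height"]
               for reg, fits in region_peaks.items() if sid in fits}
         for sid in scan_ids})
    logH = logH.reindex(columns=scan_ids)
    norm = normalize.two_pass_normalize(
        logH, _NORM_MODE[config.mode],
        intensity_ratio=config.intensity_ratio_threshold,
        presence_percentile=config.presence_percentile,
        min_peaks_per_scan=config.min_norm_peaks,
        corr_threshold=config.scan_corr_threshold,
        order=np.arange(len(scan_ids), dtype=float))
    norm_scan_ids = [sid for sid in scan_ids if sid in norm.factors.index]
    for sid in scan_ids:
        if sid not in norm.factors.index:
            removed[sid] = "no shared normalization peaks with reference"
    n_total = len(norm_scan_ids)
    _stage(stage_log, "normalization", mode=norm.mode,
           reference=str(norm.reference_scan),
           scan_correlated_peaks=len(norm.scan_correlated_peaks))

    # aggregation
    correlated = set(norm.scan_correlated_peaks)
    peaks = []
    for region_id, assigned in region_peaks.items():
        scan_peaks = []
        pooled_f, pooled_i = [], []
        for sid, (fit, (lo, hi)) in assigned.items():
            if sid not in norm.factors.index:
                continue
            fac = float(norm.factors[sid])
            scan_peaks.append(centroid.ScanPeak(
                scan_id=sid,
                center_freq=fit["center"],
                center_mz=frequency.frequency_to_mz(master, fit["center"]),
                log_height=fit["log_height"] - fac,
                height=float(np.exp(fit["log_height"] - fac)),
                area=fit["area"] * float(np.exp(-fac)),
                ssr=fit["ssr"],
                n_points=fit["n_points"],
                region_id=region_id,
                curvature=fit["curvature"],
                support=fit["support"]))
            fseg = scan_freq[sid][lo:hi + 1]
            iseg = scan_int[sid][lo:hi + 1]
            nz = iseg > 0
            pooled_f.append(fseg[nz])
            pooled_i.append(iseg[nz] * np.exp(-fac))
        if not scan_peaks:
            continue
        peak = characterize.aggregate_peak(
            region_id, (np.concatenate(pooled_f), np.concatenate(pooled_i)),
            scan_peaks, n_total_scans=n_total, model=master,
            c=config.log_constant,
            multi_peak_discards=region_discards[region_id])
        if peak is None:
            continue
        peak.offset_mz = characterize.compute_offset(
            master, peak.center_freq_fit, median_useful_diff)
        if region_id in correlated:
            peak.flags["scan_correlated"] = True
        peaks.append(peak)
    if config.mode == "filtersd":
        thr = characterize.mark_high_fsd(peaks)
        _stage(stage_log, "fsd_marking", threshold=thr,
               flagged=sum(p.flags["high_fsd"] for p in peaks))
    if config.apply_height_correction:
        characterize.correct_height_sd(peaks, n_total, rng=config.seed)
    _stage(stage_log, "characterized", peaks=len(peaks))

    model_by_scan = {m.source_scan: m for m in models}
    scan_table = pd.DataFrame(
        [{"scan_id": s.scan_id, "rt": s.rt,
          "sqrt_coefficient": model_by_scan[s.scan_id].y,
          "r2": model_by_scan[s.scan_id].r2,
          "factor": float(norm.factors.get(s.scan_id, np.nan))}
         for s in scans_kept])
    return PipelineResult(peaks=peaks, normalization=norm,
                          master_model=master,
                          point_spacing=point_spacing,
                          median_useful_diff=median_useful_diff,
                          noise_cutoff=cutoff,
                          n_initial_regions=len(initial),
                          scan_table=scan_table, removed_scans=removed,
                          stage_log=stage_log, config=config,
                          sample_id=scanset.sample_id)
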