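"""Reading profile mzML, acquisition-level scan filtering, and writing
characterized-peak output (JSON metadata + peaks, companion CSV table)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ProfileScan", "ScanSet", "ScanIOError", "read_profile_mzml",
           "filter_scans", "write_characterized_peaks",
           "read_characterized_peaks", "read_centroid_list"]

log = logging.getLogger(__name__)


class ScanIOError(RuntimeError):
    pass


@dataclass
class ProfileScan:
    """One scan's profile arrays plus acquisition metadata.

    m/z strictly increasing; intensities non-negative, same length; zero
    intensities are preserved on read because the instrument's flooring
    zeros carry the noise structure used downstream.
    """

    scan_id: object
    rt: float                 # seconds
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"scan {self.scan_id}: m/z and intensity lengths differ "
                f"({self.mz.size} vs {self.intensity.size})")
        if np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_id}: negative intensities")

    @property
    def n_points(self) -> int:
        return int(self.mz.size)


@dataclass
class ScanSet:
    scans: list
    sample_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.rt)

    def __len__(self):
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    def scan_ids(self) -> list:
        return [s.scan_id for s in self.scans]


def read_profile_mzml(path) -> ScanSet:
    """All MS1 profile scans of an mzML file, arrays ascending in m/z.

    Centroided-only files and files without MS1 scans raise ScanIOError.
    """
    from ._mzml import read_mzml_spectra

    path = Path(path)
    if not path.exists():
        raise ScanIOError(f"mzML file not found: {path}")
    scans = []
    saw_centroid_only = False
    try:
        for spec in read_mzml_spectra(path):
            if spec["ms_level"] != 1:
                continue
            if spec["mode"] == "centroid":
                saw_centroid_only = True
                continue
            if spec["mz"] is None or spec["intensity"] is None:
                continue
            rt = spec["rt"] if spec["rt"] is not None else float(len(scans))
            scans.append(ProfileScan(
                scan_id=spec["id"] or f"scan={len(scans)}",
                rt=rt, ms_level=1,
                mz=spec["mz"], intensity=spec["intensity"]))
    except ScanIOError:
        raise
    except Exception as exc:  # malformed XML, bad encoding, ...
        raise ScanIOError(f"unreadable mzML file {path}: {exc}") from exc
    if not scans:
        if saw_centroid_only:
            raise ScanIOError(
                f"{path} contains only centroided MS1 spectra; profile "
                "mode is required")
        raise ScanIOError(f"no MS1 scans in {path}")
    return ScanSet(scans=scans, sample_id=path.stem,
                   provenance={"source": str(path), "filter_log": []})


def filter_scans(scanset: ScanSet, min_gap_s: float = 4.0,
                 max_rt_s: float | None = None) -> ScanSet:
    """Greedy acquisition-time filter.

    Keeps the first scan, then every scan whose retention time differs from
    the last KEPT scan by at least ``min_gap_s``; scans at or beyond
    ``max_rt_s`` (when set) are dropped first.  Idempotent.  Raises when
    nothing survives.
    """
    decisions = []
    kept = []
    last_rt = None
    for scan in scanset.scans:
        if max_rt_s is not None and scan.rt >= max_rt_s:
            decisions.append((scan.scan_id, "dropped: rt >= max_rt"))
            continue
        if last_rt is None or scan.rt - last_rt >= min_gap_s:
            kept.append(scan)
            last_rt = scan.rt
            decisions.append((scan.scan_id, "kept"))
        else:
            decisions.append((scan.scan_id, "dropped: gap < min_gap"))
    if not kept:
        raise ScanIOError("all scans removed by acquisition filters")
    prov = dict(scanset.provenance)
    prov["filter_log"] = list(prov.get("filter_log", [])) + decisions
    return ScanSet(scans=kept, sample_id=scanset.sample_id, provenance=prov)


_PEAK_COLUMNS = [
    "peak_id", "center_mz_fit", "center_freq_fit", "center_freq_mean",
    "center_freq_sd", "height_fit", "height_mean", "height_sd",
    "height_mean_corrected", "height_sd_corrected", "n_scans",
    "scan_fraction", "offset_mz", "area_mean", "high_fsd",
    "scan_correlated", "low_replication", "multi_peak_discarded_scans",
]


def write_characterized_peaks(peaks, meta: dict, json_path,
                              csv_path=None) -> None:
    """JSON document (metadata + full peak records) and companion flat CSV.

    JSON floats use repr serialization, so a read-back is bit-exact.
    """
    json_path = Path(json_path)
    records = [p.to_dict(with_scan_heights=True) for p in peaks]
    doc = {"metadata": meta, "peaks": records}
    try:
        json_path.parent.mkdir(parents=True, exist_ok=True)
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=1, allow_nan=True, default=str)
    except OSError as exc:
        raise ScanIOError(f"cannot write {json_path}: {exc}") from exc
    if csv_path is not None:
        rows = []
        for r in records:
            row = {k: r.get(k) for k in _PEAK_COLUMNS if k in r}
            flags = r.get("flags", {})
            row["high_fsd"] = bool(flags.get("high_fsd", False))
            row["scan_correlated"] = bool(flags.get("scan_correlated", False))
            row["low_replication"] = bool(flags.get("low_replication", False))
            row["multi_peak_discarded_scans"] = int(
                flags.get("multi_peak_discarded_scans", 0))
            rows.append(row)
        pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(csv_path,
                                                         index=False)


def read_characterized_peaks(json_path) -> dict:
    """Read back a characterized-peak JSON document (losslessly for every
    numeric field)."""
    with open(json_path) as fh:
        return json.load(fh)


_MZ_NAMES = {"mz", "m/z", "m_z", "mass", "m.z"}
_INT_NAMES = {"intensity", "int", "height", "abundance"}


def read_centroid_list(path) -> list:
    """(m/z, intensity) pairs from a delimited text centroid list, ordered
    by m/z.  The delimiter is sniffed; column names are matched
    case-insensitively against common m/z / intensity spellings."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ScanIOError(f"unreadable centroid list {path}: {exc}") from exc
    cols = {str(c).strip().lower(): c for c in df.columns}
    mz_col = next((cols[k] for k in cols if k in _MZ_NAMES), None)
    int_col = next((cols[k] for k in cols if k in _INT_NAMES), None)
    if mz_col is None or int_col is None:
        raise ScanIOError(
            f"centroid list {path} must have m/z and intensity columns; "
            f"found {list(df.columns)}")
    for col in (mz_col, int_col):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise ScanIOError(
                f"non-numeric value(s) in column {col!r} of {path} at "
                f"row(s) {rows}")
    df = df[[mz_col, int_col]].dropna().astype(float)
    df = df.sort_values(mz_col, kind="stable")
    return list(df.itertuples(index=False, name=None))
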