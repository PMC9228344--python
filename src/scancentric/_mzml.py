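"""Minimal mzML reading and writing for profile MS1 spectra.

The reader streams ``<spectrum>`` elements with lxml and interprets the
PSI-MS controlled-vocabulary terms the pipeline needs: ms level, profile /
centroid spectrum, scan start time (with minute/second units), binary array
type (m/z or intensity), precision (32/64-bit float) and compression (zlib
or none).  The writer emits a plain (non-indexed) mzML 1.1 document with
64-bit, zlib-compressed, base64-encoded arrays.  Together they cover
msconvert-style profile files and the package's synthetic fixtures — not
the full breadth of the standard (no chromatograms, no numpress).
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree

__all__ = ["read_mzml_spectra", "write_mzml"]

# PSI-MS accessions understood by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_CENTROID = "MS:1000127"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray | None]:
    """(array kind, values) from a <binaryDataArray> element."""
    dtype = "<f8"
    compressed = False
    kind = None
    payload = None
    for el in bda.iter():
        name = _local(el.tag)
        if name == "cvParam":
            acc = el.get("accession", "")
            if acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif name == "binary":
            payload = el.text or ""
    if kind is None or payload is None:
        return None, None
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_spectra(path):
    """Iterate spectra of an mzML file as dicts with keys ``id``,
    ``ms_level``, ``mode`` ('profile' | 'centroid' | None), ``rt`` (seconds,
    None when absent), ``mz`` and ``intensity`` arrays."""
    context = etree.iterparse(str(path), events=("end",))
    for _, elem in context:
        if _local(elem.tag) != "spectrum":
            continue
        spec = {"id": elem.get("id", ""), "ms_level": None, "mode": None,
                "rt": None, "mz": None, "intensity": None}
        for el in elem.iter():
            name = _local(el.tag)
            if name == "cvParam":
                acc = el.get("accession", "")
                if acc == _ACC_MS_LEVEL:
                    spec["ms_level"] = int(el.get("value"))
                elif acc == _ACC_PROFILE:
                    spec["mode"] = "profile"
                elif acc == _ACC_CENTROID and spec["mode"] is None:
                    spec["mode"] = "centroid"
                elif acc == _ACC_SCAN_START:
                    rt = float(el.get("value"))
                    unit = (el.get("unitName") or "").lower()
                    spec["rt"] = rt * 60.0 if unit.startswith("min") else rt
            elif name == "binaryDataArray":
                kind, values = _decode_binary_array(el)
                if kind:
                    spec[kind] = values
        yield spec
        elem.clear()

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode(arr: np.ndarray) -> str:
    raw = np.asarray(arr, dtype="<f8").tobytes()
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _binary_array(data: str, kind_accession: str, kind_name: str) -> str:
    return f"""          <binaryDataArray encodedLength="{len(data)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="{kind_accession}" name="{kind_name}" value=""/>
            <binary>{data}</binary>
          </binaryDataArray>
"""


def write_mzml(scanset, path) -> None:
    """Write a ScanSet as profile MS1 mzML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    parts = [_HEADER.format(run_id=escape(str(scanset.sample_id or "run")),
                            count=len(scanset.scans))]
    for i, scan in enumerate(scanset.scans):
        mz_b64 = _encode(scan.mz)
        int_b64 = _encode(scan.intensity)
        parts.append(f"""      <spectrum index="{i}" id="{escape(str(scan.scan_id))}" defaultArrayLength="{scan.n_points}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{scan.ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
{_binary_array(mz_b64, "MS:1000514", "m/z array")}{_binary_array(int_b64, "MS:1000515", "intensity array")}        </binaryDataArrayList>
      </spectrum>
""")
    parts.append(_FOOTER)
    path.write_text("".join(parts))
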