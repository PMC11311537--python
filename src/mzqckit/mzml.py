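"""Optional mzML reader built on lxml.

Maps mzML spectra onto the toolkit's :class:`~mzqckit.metrics.Run` /
:class:`~mzqckit.metrics.Spectrum` containers: MS level, scan start time
(unit-converted to seconds), precursor m/z and charge, ion injection time
(milliseconds), the decoded peak arrays (32/64-bit floats, zlib or
uncompressed), and the run's chromatogram count. It reads the subset of
mzML that carries these quantities and ignores the rest; it is not a
general mzML object model.
"""

from __future__ import annotations

import base64
import os
import struct
import zlib
from typing import Optional, Union

import numpy as np
from lxml import etree

from .metrics import MetricError, Run, Spectrum

__all__ = ["read_mzml"]

_NS = "{http://psi.hupo.org/ms/mzml}"

# accessions interpreted below
_MS_LEVEL = "MS:1000511"
_SCAN_START = "MS:1000016"
_INJECTION = "MS:1000927"
_SELECTED_MZ = "MS:1000744"
_CHARGE = "MS:1000041"
_MZ_ARRAY = "MS:1000514"
_INT_ARRAY = "MS:1000515"
_F64 = "MS:1000523"
_F32 = "MS:1000521"
_ZLIB = "MS:1000574"
_NO_COMPRESSION = "MS:1000576"

_TIME_FACTORS = {
    "second": 1.0,
    "minute": 60.0,
    "millisecond": 1e-3,
    None: 1.0,
}


def _cv_params(elem) -> dict[str, dict]:
    """accession -> {value, unitName} over direct cvParam children."""
    out = {}
    for cv in elem.findall(f"{_NS}cvParam"):
        out[cv.get("accession")] = {
            "value": cv.get("value"),
            "unit": cv.get("unitName"),
        }
    return out


def _decode_binary(array_elem) -> np.ndarray:
    params = _cv_params(array_elem)
    binary = array_elem.find(f"{_NS}binary")
    if binary is None or not (binary.text or "").strip():
        return np.asarray([], dtype=float)
    raw = base64.b64decode(binary.text)
    if _ZLIB in params:
        raw = zlib.decompress(raw)
    width = "f" if _F32 in params else "d"
    count = len(raw) // struct.calcsize(width)
    return np.asarray(struct.unpack(f"<{count}{width}", raw), dtype=float)


def _read_spectrum(elem) -> Spectrum:
    params = _cv_params(elem)
    ms_level = int(params.get(_MS_LEVEL, {}).get("value", 1))

    rt = 0.0
    injection: Optional[float] = None
    scan_list = elem.find(f"{_NS}scanList")
    if scan_list is not None:
        for scan in scan_list.findall(f"{_NS}scan"):
            scan_params = _cv_params(scan)
            if _SCAN_START in scan_params:
                entry = scan_params[_SCAN_START]
                factor = _TIME_FACTORS.get(entry["unit"])
                if factor is None:
                    raise MetricError(f"unsupported time unit {entry['unit']!r}")
                rt = float(entry["value"]) * factor
            if _INJECTION in scan_params and injection is None:
                injection = float(scan_params[_INJECTION]["value"])

    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    for ion in elem.iter(f"{_NS}selectedIon"):
        ion_params = _cv_params(ion)
        if _SELECTED_MZ in ion_params:
            precursor_mz = float(ion_params[_SELECTED_MZ]["value"])
        if _CHARGE in ion_params:
            precursor_charge = int(ion_params[_CHARGE]["value"])
        break

    mz = intensity = np.asarray([], dtype=float)
    for array_elem in elem.iter(f"{_NS}binaryDataArray"):
        params = _cv_params(array_elem)
        if _MZ_ARRAY in params:
            mz = _decode_binary(array_elem)
        elif _INT_ARRAY in params:
            intensity = _decode_binary(array_elem)

    return Spectrum(
        native_id=elem.get("id"),
        ms_level=ms_level,
        rt_seconds=rt,
        mz_array=mz,
        intensity_array=intensity,
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        injection_time_ms=injection,
    )


def read_mzml(path: Union[str, os.PathLike], run_name: Optional[str] = None) -> Run:
    """Read an mzML file into a :class:`Run`."""
    path = os.fspath(path)
    spectra: list[Spectrum] = []
    n_chrom = 0
    for _, elem in etree.iterparse(
        path, events=("end",), tag=(f"{_NS}spectrum", f"{_NS}chromatogram")
    ):
        if elem.tag == f"{_NS}spectrum":
            spectra.append(_read_spectrum(elem))
        else:
            n_chrom += 1
        elem.clear()
    name = run_name or os.path.splitext(os.path.basename(path))[0]
    return Run(
        run_name=name,
        source_location=f"file://{os.path.abspath(path)}",
        spectra=spectra,
        chromatogram_count=n_chrom,
    )
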