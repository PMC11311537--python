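"""Read and write mzQC documents as JSON.

The on-disk form is a JSON object whose single root key is ``"mzQC"``.
Reading is tolerant: unknown keys anywhere in the file are preserved on the
model objects (in their ``extras`` dict) and re-emitted verbatim on write,
so files produced by newer format revisions survive a round-trip. Writing
is strict: optional fields that are absent are omitted rather than emitted
as ``null``, and a document that violates the model invariants is refused.
Structural — not byte-wise — round-trip equality is the contract.
"""

from __future__ import annotations

import json
import os
from typing import Any, Optional, Union

from .model import (
    CvParam,
    CvReference,
    InputFile,
    Metadata,
    MetricValue,
    ModelError,
    MzQcDocument,
    QualityElement,
    QualityMetric,
    RUN_LEVEL,
    SET_LEVEL,
    SoftwareRef,
)

__all__ = ["FormatError", "read_mzqc", "read_mzqc_file", "write_mzqc", "write_mzqc_file"]


class FormatError(ValueError):
    """The text is JSON but not an mzQC document."""


def _extras(obj: dict, known: tuple[str, ...]) -> dict:
    return {k: v for k, v in obj.items() if k not in known}


def _require(obj: dict, key: str, path: str) -> Any:
    if key not in obj:
        raise FormatError(f"{path}: missing required key {key!r}")
    return obj[key]


def _cv_param(obj: dict, path: str) -> CvParam:
    known = ("accession", "name", "value")
    return CvParam(
        accession=_require(obj, "accession", path),
        name=_require(obj, "name", path),
        value=obj.get("value"),
        extras=_extras(obj, known),
    )


def _input_file(obj: dict, path: str) -> InputFile:
    known = ("name", "location", "fileFormat", "fileProperties")
    fmt = obj.get("fileFormat")
    props = obj.get("fileProperties")
    return InputFile(
        name=_require(obj, "name", path),
        location=_require(obj, "location", path),
        fileFormat=_cv_param(fmt, f"{path}/fileFormat") if fmt is not None else None,
        fileProperties=(
            [_cv_param(p, f"{path}/fileProperties/{i}") for i, p in enumerate(props)]
            if props is not None
            else None
        ),
        extras=_extras(obj, known),
    )


def _software(obj: dict, path: str) -> SoftwareRef:
    known = ("accession", "name", "version", "uri")
    return SoftwareRef(
        accession=_require(obj, "accession", path),
        name=_require(obj, "name", path),
        version=_require(obj, "version", path),
        uri=obj.get("uri"),
        extras=_extras(obj, known),
    )


def _metadata(obj: dict, path: str) -> Metadata:
    known = ("inputFiles", "analysisSoftware", "label", "cvParameters")
    params = obj.get("cvParameters")
    return Metadata(
        inputFiles=[
            _input_file(f, f"{path}/inputFiles/{i}")
            for i, f in enumerate(_require(obj, "inputFiles", path))
        ],
        analysisSoftware=[
            _software(s, f"{path}/analysisSoftware/{i}")
            for i, s in enumerate(_require(obj, "analysisSoftware", path))
        ],
        label=obj.get("label"),
        cvParameters=(
            [_cv_param(p, f"{path}/cvParameters/{i}") for i, p in enumerate(params)]
            if params is not None
            else None
        ),
        extras=_extras(obj, known),
    )


def _metric(obj: dict, path: str) -> QualityMetric:
    known = ("accession", "name", "description", "value", "unit")
    unit = obj.get("unit")
    parsed_unit: Optional[Union[CvParam, list[CvParam]]]
    if unit is None:
        parsed_unit = None
    elif isinstance(unit, list):
        parsed_unit = [_cv_param(u, f"{path}/unit/{i}") for i, u in enumerate(unit)]
    else:
        parsed_unit = _cv_param(unit, f"{path}/unit")
    try:
        value = MetricValue.from_raw(_require(obj, "value", path))
    except ModelError as exc:
        raise ModelError(str(exc), f"{path}/value") from exc
    return QualityMetric(
        accession=_require(obj, "accession", path),
        name=_require(obj, "name", path),
        value=value,
        description=obj.get("description"),
        unit=parsed_unit,
        extras=_extras(obj, known),
    )


def _element(obj: dict, kind: str, path: str) -> QualityElement:
    known = ("metadata", "qualityMetrics")
    return QualityElement(
        metadata=_metadata(_require(obj, "metadata", path), f"{path}/metadata"),
        qualityMetrics=[
            _metric(m, f"{path}/qualityMetrics/{i}")
            for i, m in enumerate(_require(obj, "qualityMetrics", path))
        ],
        kind=kind,
        extras=_extras(obj, known),
    )


def _cv_ref(obj: dict, path: str) -> CvReference:
    known = ("name", "uri", "version")
    return CvReference(
        name=_require(obj, "name", path),
        uri=_require(obj, "uri", path),
        version=obj.get("version"),
        extras=_extras(obj, known),
    )


def read_mzqc(text: str, strict: bool = True) -> MzQcDocument:
    """Deserialize mzQC JSON text into an :class:`MzQcDocument`.

    Parameters
    ----------
    text:
        JSON text whose root object holds the document under the key
        ``"mzQC"``.
    strict:
        When true (default) the assembled document is invariant-checked and
        a violation raises :class:`~mzqckit.model.ModelError` carrying the
        offending path. ``strict=False`` skips the check, which lets
        deliberately non-conforming documents be materialized for
        validation workflows.
    """
    root = json.loads(text)
    if not isinstance(root, dict) or "mzQC" not in root:
        raise FormatError("missing mzQC root")
    body = root["mzQC"]
    if not isinstance(body, dict):
        raise FormatError("mzQC root is not an object")
    known = (
        "version",
        "creationDate",
        "description",
        "contactName",
        "contactAddress",
        "controlledVocabularies",
        "runQualities",
        "setQualities",
    )
    doc = MzQcDocument(
        version=_require(body, "version", "mzQC"),
        creationDate=_require(body, "creationDate", "mzQC"),
        controlledVocabularies=[
            _cv_ref(r, f"mzQC/controlledVocabularies/{i}")
            for i, r in enumerate(_require(body, "controlledVocabularies", "mzQC"))
        ],
        runQualities=[
            _element(e, RUN_LEVEL, f"mzQC/runQualities/{i}")
            for i, e in enumerate(body.get("runQualities", []))
        ],
        setQualities=[
            _element(e, SET_LEVEL, f"mzQC/setQualities/{i}")
            for i, e in enumerate(body.get("setQualities", []))
        ],
        description=body.get("description"),
        contactName=body.get("contactName"),
        contactAddress=body.get("contactAddress"),
        extras=_extras(body, known),
    )
    if strict:
        doc.check()
    return doc


def read_mzqc_file(path: Union[str, os.PathLike], strict: bool = True) -> MzQcDocument:
    """Read an mzQC document from a local file (conventionally ``.mzQC``/``.mzqc``).

    Remote locations are deliberately not fetched; callers wanting remote
    documents retrieve the text themselves and use :func:`read_mzqc`.
    """
    with open(path, "r", encoding="utf-8") as handle:
        return read_mzqc(handle.read(), strict=strict)


def _emit_param(p: CvParam) -> dict:
    out: dict[str, Any] = {"accession": p.accession, "name": p.name}
    if p.value is not None:
        out["value"] = p.value
    out.update(p.extras)
    return out


def _emit_input_file(f: InputFile) -> dict:
    out: dict[str, Any] = {"name": f.name, "location": f.location}
    if f.fileFormat is not None:
        out["fileFormat"] = _emit_param(f.fileFormat)
    if f.fileProperties is not None:
        out["fileProperties"] = [_emit_param(p) for p in f.fileProperties]
    out.update(f.extras)
    return out


def _emit_software(s: SoftwareRef) -> dict:
    out: dict[str, Any] = {"accession": s.accession, "name": s.name, "version": s.version}
    if s.uri is not None:
        out["uri"] = s.uri
    out.update(s.extras)
    return out


def _emit_metadata(md: Metadata) -> dict:
    out: dict[str, Any] = {
        "inputFiles": [_emit_input_file(f) for f in md.inputFiles],
        "analysisSoftware": [_emit_software(s) for s in md.analysisSoftware],
    }
    if md.label is not None:
        out["label"] = md.label
    if md.cvParameters is not None:
        out["cvParameters"] = [_emit_param(p) for p in md.cvParameters]
    out.update(md.extras)
    return out


def _emit_metric(m: QualityMetric) -> dict:
    out: dict[str, Any] = {"accession": m.accession, "name": m.name}
    if m.description is not None:
        out["description"] = m.description
    out["value"] = m.value.to_json()
    if m.unit is not None:
        if isinstance(m.unit, list):
            out["unit"] = [_emit_param(u) for u in m.unit]
        else:
            out["unit"] = _emit_param(m.unit)
    out.update(m.extras)
    return out


def _emit_element(e: QualityElement) -> dict:
    out: dict[str, Any] = {
        "metadata": _emit_metadata(e.metadata),
        "qualityMetrics": [_emit_metric(m) for m in e.qualityMetrics],
    }
    out.update(e.extras)
    return out


def _emit_cv_ref(r: CvReference) -> dict:
    out: dict[str, Any] = {"name": r.name, "uri": r.uri}
    if r.version is not None:
        out["version"] = r.version
    out.update(r.extras)
    return out


def write_mzqc(doc: MzQcDocument, indent: Optional[int] = 2) -> str:
    """Serialize a document to mzQC JSON text.

    The document is invariant-checked first; serialization of an invalid
    document is refused. Numbers are emitted with Python's shortest
    round-trippable decimal representation, preserving metric fidelity.
    """
    doc.check()
    body: dict[str, Any] = {
        "version": doc.version,
        "creationDate": doc.creationDate,
    }
    if doc.description is not None:
        body["description"] = doc.description
    if doc.contactName is not None:
        body["contactName"] = doc.contactName
    if doc.contactAddress is not None:
        body["contactAddress"] = doc.contactAddress
    body["controlledVocabularies"] = [_emit_cv_ref(r) for r in doc.controlledVocabularies]
    if doc.runQualities:
        body["runQualities"] = [_emit_element(e) for e in doc.runQualities]
    if doc.setQualities:
        body["setQualities"] = [_emit_element(e) for e in doc.setQualities]
    body.update(doc.extras)
    return json.dumps({"mzQC": body}, indent=indent, ensure_ascii=False)


def write_mzqc_file(doc: MzQcDocument, path: Union[str, os.PathLike]) -> None:
    """Write a document to ``path`` as mzQC JSON."""
    text = write_mzqc(doc)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(text)
        handle.write("\n")
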