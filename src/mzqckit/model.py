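"""In-memory data model for mzQC documents.

The mzQC format stores mass-spectrometry quality-control metrics as JSON.
Metrics live in ``runQuality`` elements (one MS run) or ``setQuality``
elements (a set of runs); every metric is anchored to a controlled-vocabulary
term by its accession, and metric values are scalars, tuples, or columnar
tables. This module provides typed containers for the format together with
construction-time invariant checks. It deliberately passes no judgment on
metric values — the format communicates quality information, it does not
grade it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "ModelError",
    "SUPPORTED_VERSION",
    "ACCESSION_PATTERN",
    "VERSION_PATTERN",
    "TIMESTAMP_PATTERN",
    "MetricValue",
    "classify_value",
    "CvParam",
    "CvReference",
    "SoftwareRef",
    "InputFile",
    "Metadata",
    "QualityMetric",
    "QualityElement",
    "MzQcDocument",
    "new_document",
    "add_metric",
]


class ModelError(ValueError):
    """An mzQC invariant was violated; the message names the invariant."""

    def __init__(self, message: str, path: str = "") -> None:
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)


#: The only format version this toolkit targets.
SUPPORTED_VERSION = "1.0.0"

#: CV accessions look like ``MS:4000059`` — an uppercase alphanumeric prefix
#: (starting with a letter), a colon, and digits. The pattern is deliberately
#: not tied to one prefix so that local vocabularies validate too.
ACCESSION_PATTERN = re.compile(r"^[A-Z]+[A-Z0-9]*:[0-9]+$")

VERSION_PATTERN = re.compile(r"^\d+\.\d+\.\d+$")

#: ISO-8601 date+time with seconds; fractional seconds and an offset are
#: accepted. Timestamps are stored verbatim (no timezone normalization) so
#: that read/write round-trips are faithful.
TIMESTAMP_PATTERN = re.compile(
    r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(\.\d+)?(Z|[+-]\d{2}:\d{2})?$"
)

_SCALAR_TYPES = (bool, int, float, str)

Scalar = Union[bool, int, float, str]


def classify_value(raw: Any) -> str:
    """Classify a JSON-representable metric value as scalar, tuple, or table.

    Mapping-of-equal-length-lists -> ``"table"``; list of scalars ->
    ``"tuple"``; atom -> ``"scalar"``. Null values and ragged tables are
    rejected: a metric without a well-formed value carries no QC information.
    """
    if raw is None:
        raise ModelError("null metric value")
    if isinstance(raw, _SCALAR_TYPES):
        return "scalar"
    if isinstance(raw, Sequence) and not isinstance(raw, (str, bytes)):
        if len(raw) < 1:
            raise ModelError("empty tuple value")
        for item in raw:
            if not isinstance(item, _SCALAR_TYPES):
                raise ModelError("tuple elements must be scalars")
        return "tuple"
    if isinstance(raw, Mapping):
        if not raw:
            raise ModelError("empty table value")
        lengths = set()
        for col, cells in raw.items():
            if not isinstance(cells, Sequence) or isinstance(cells, (str, bytes)):
                raise ModelError(f"table column {col!r} is not a list")
            lengths.add(len(cells))
        if len(lengths) != 1:
            raise ModelError("ragged table")
        if lengths == {0}:
            raise ModelError("table columns must be non-empty")
        return "table"
    raise ModelError(f"unsupported metric value of type {type(raw).__name__}")


@dataclass
class MetricValue:
    """A metric value with its classified kind.

    ``data`` keeps the JSON-native representation (atom, list, or mapping of
    column-name to equal-length lists) so serialization is lossless; tables
    are additionally exposed as a pandas DataFrame via :meth:`as_dataframe`.
    """

    kind: str
    data: Any

    @classmethod
    def from_raw(cls, raw: Any) -> "MetricValue":
        return cls(kind=classify_value(raw), data=raw)

    def as_dataframe(self) -> pd.DataFrame:
        if self.kind != "table":
            raise ModelError("only table values convert to a DataFrame")
        return pd.DataFrame(dict(self.data))

    def to_json(self) -> Any:
        return self.data


@dataclass
class CvParam:
    """A CV-anchored parameter (accession + name, optional value)."""

    accession: str
    name: str
    value: Optional[Scalar] = None
    extras: dict = field(default_factory=dict)


@dataclass
class CvReference:
    """One entry of the document's controlled-vocabulary list."""

    name: str
    uri: str
    version: Optional[str] = None
    extras: dict = field(default_factory=dict)


@dataclass
class SoftwareRef:
    """The software that computed a group of metrics."""

    accession: str
    name: str
    version: str
    uri: Optional[str] = None
    extras: dict = field(default_factory=dict)


@dataclass
class InputFile:
    """An input MS data file whose quality the element describes."""

    name: str
    location: str
    fileFormat: Optional[CvParam] = None
    fileProperties: Optional[list[CvParam]] = None
    extras: dict = field(default_factory=dict)


@dataclass
class Metadata:
    """Provenance of a quality element: input files and analysis software."""

    inputFiles: list[InputFile]
    analysisSoftware: list[SoftwareRef]
    label: Optional[str] = None
    cvParameters: Optional[list[CvParam]] = None
    extras: dict = field(default_factory=dict)


@dataclass
class QualityMetric:
    """One CV-anchored quality metric."""

    accession: str
    name: str
    value: MetricValue
    description: Optional[str] = None
    unit: Optional[Union[CvParam, list[CvParam]]] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.value, MetricValue):
            self.value = MetricValue.from_raw(self.value)


RUN_LEVEL = "runQuality"
SET_LEVEL = "setQuality"


@dataclass
class QualityElement:
    """A runQuality or setQuality element: metadata plus its metrics."""

    metadata: Metadata
    qualityMetrics: list[QualityMetric]
    kind: str = RUN_LEVEL
    extras: dict = field(default_factory=dict)


@dataclass
class MzQcDocument:
    """Root of an mzQC file."""

    version: str
    creationDate: str
    controlledVocabularies: list[CvReference]
    runQualities: list[QualityElement] = field(default_factory=list)
    setQualities: list[QualityElement] = field(default_factory=list)
    description: Optional[str] = None
    contactName: Optional[str] = None
    contactAddress: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def check(self) -> None:
        """Raise :class:`ModelError` on the first violated invariant."""
        for path, message in iter_violations(self):
            raise ModelError(message, path)

    def all_elements(self) -> Iterator[tuple[str, QualityElement]]:
        """Yield ``(path, element)`` for every quality element."""
        for i, elem in enumerate(self.runQualities):
            yield f"mzQC/runQualities/{i}", elem
        for i, elem in enumerate(self.setQualities):
            yield f"mzQC/setQualities/{i}", elem


def _check_accession(acc: Any, path: str) -> Iterator[tuple[str, str]]:
    if not isinstance(acc, str) or not ACCESSION_PATTERN.match(acc):
        yield path, f"malformed accession {acc!r}"


def iter_violations(doc: MzQcDocument) -> Iterator[tuple[str, str]]:
    """Yield ``(path, message)`` for every violated document invariant.

    Paths use slash notation with zero-based list indices, rooted at
    ``mzQC`` — e.g. ``mzQC/runQualities/0/qualityMetrics/2``.
    """
    if not VERSION_PATTERN.match(doc.version or ""):
        yield "mzQC/version", f"malformed version {doc.version!r}"
    elif doc.version != SUPPORTED_VERSION:
        yield "mzQC/version", (
            f"unsupported version {doc.version!r} (this toolkit targets "
            f"{SUPPORTED_VERSION})"
        )
    if not TIMESTAMP_PATTERN.match(doc.creationDate or ""):
        yield "mzQC/creationDate", f"malformed timestamp {doc.creationDate!r}"
    if not doc.controlledVocabularies:
        yield "mzQC/controlledVocabularies", "no controlled vocabularies"
    for i, ref in enumerate(doc.controlledVocabularies):
        if not ref.name or not ref.uri:
            yield (
                f"mzQC/controlledVocabularies/{i}",
                "CV reference needs non-empty name and uri",
            )
    if not doc.runQualities and not doc.setQualities:
        yield "mzQC", "no quality elements"
    for path, elem in doc.all_elements():
        yield from _element_violations(path, elem)


def _element_violations(path: str, elem: QualityElement) -> Iterator[tuple[str, str]]:
    md = elem.metadata
    if not md.inputFiles:
        yield f"{path}/metadata/inputFiles", "no input files"
    elif elem.kind == SET_LEVEL and len(md.inputFiles) < 2:
        yield (
            f"{path}/metadata/inputFiles",
            "set-level element must reference at least 2 input files",
        )
    seen_files: set[str] = set()
    for i, f in enumerate(md.inputFiles):
        if not f.name or not f.location:
            yield (
                f"{path}/metadata/inputFiles/{i}",
                "input file needs non-empty name and location",
            )
        if f.name in seen_files:
            yield (
                f"{path}/metadata/inputFiles/{i}",
                f"duplicate input file name {f.name!r}",
            )
        seen_files.add(f.name)
    if not md.analysisSoftware:
        yield f"{path}/metadata/analysisSoftware", "no analysis software"
    for i, sw in enumerate(md.analysisSoftware):
        yield from _check_accession(sw.accession, f"{path}/metadata/analysisSoftware/{i}")
    if not elem.qualityMetrics:
        yield f"{path}/qualityMetrics", "no quality metrics"
    seen_acc: set[str] = set()
    for i, metric in enumerate(elem.qualityMetrics):
        mpath = f"{path}/qualityMetrics/{i}"
        yield from _check_accession(metric.accession, mpath)
        if metric.accession in seen_acc:
            yield mpath, f"duplicate metric accession {metric.accession!r}"
        seen_acc.add(metric.accession)
        try:
            classify_value(metric.value.data)
        except ModelError as exc:
            yield mpath, str(exc)


def new_document(
    version: str,
    creationDate: str,
    cvRefs: Sequence[CvReference],
    runQualities: Sequence[QualityElement] = (),
    setQualities: Sequence[QualityElement] = (),
    **optional: Any,
) -> MzQcDocument:
    """Build and invariant-check an :class:`MzQcDocument`.

    Raises :class:`ModelError` naming the violated invariant (and the path
    at which it occurs) when construction would produce an invalid document.
    """
    doc = MzQcDocument(
        version=version,
        creationDate=creationDate,
        controlledVocabularies=list(cvRefs),
        runQualities=list(runQualities),
        setQualities=list(setQualities),
        **optional,
    )
    doc.check()
    return doc


def add_metric(element: QualityElement, metric: QualityMetric) -> QualityElement:
    """Append ``metric`` to ``element`` in place, preserving accession uniqueness.

    Returns the element for chaining. A second metric with an accession that
    the element already holds is refused (``duplicate metric``).
    """
    if any(m.accession == metric.accession for m in element.qualityMetrics):
        raise ModelError(f"duplicate metric accession {metric.accession!r}")
    classify_value(metric.value.data)
    element.qualityMetrics.append(metric)
    return element
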