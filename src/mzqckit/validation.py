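"""Syntactic validation of mzQC text against the format's structure rules.

The validator works on the raw JSON tree (never on model objects, which could
not even hold many of the defects it must report), collects every finding
rather than failing fast, and never raises: malformed JSON is itself a
finding (rule ``not-json``). Findings carry a stable rule id, a severity,
and a slash-delimited path with zero-based list indices rooted at ``mzQC``.

Rule ids emitted here:

========================  ======================================================
``not-json``              the text is not well-formed JSON
``missing-root``          no ``"mzQC"`` root object
``required-missing``      a required key is absent
``type-mismatch``         a field holds the wrong JSON type
``bad-version``           version does not match ``digits.digits.digits``
``bad-timestamp``         creationDate is not ISO-8601 date+time
``bad-accession``         an accession does not match ``PREFIX:digits``
``no-quality-elements``   neither runQualities nor setQualities is non-empty
``empty-list``            a list that must be non-empty is empty
``empty-metrics``         a quality element carries no metrics
``duplicate-metric``      repeated metric accession within one element
``ragged-table``          table columns of unequal length
``bad-value``             a metric value is null or not scalar/tuple/table
========================  ======================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

from .model import ACCESSION_PATTERN, TIMESTAMP_PATTERN, VERSION_PATTERN

__all__ = ["ValidationFinding", "ValidationReport", "validate_syntax"]

ERROR = "error"
WARNING = "warning"


@dataclass(frozen=True)
class ValidationFinding:
    """One problem found in a document."""

    rule_id: str
    severity: str
    path: str
    message: str

    def to_json(self) -> dict:
        return {
            "ruleId": self.rule_id,
            "severity": self.severity,
            "path": self.path,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    """All findings for one document; valid iff no error-severity finding."""

    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(f.severity == ERROR for f in self.findings)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == ERROR]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == WARNING]

    def rule_ids(self) -> set[str]:
        return {f.rule_id for f in self.findings}

    def to_json(self) -> dict:
        return {"valid": self.valid, "findings": [f.to_json() for f in self.findings]}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        verdict = "valid" if self.valid else "invalid"
        return f"<ValidationReport {verdict}, {len(self.findings)} finding(s)>"


class _Collector:
    def __init__(self) -> None:
        self.findings: list[ValidationFinding] = []

    def add(self, rule: str, path: str, message: str, severity: str = ERROR) -> None:
        self.findings.append(ValidationFinding(rule, severity, path, message))

    # -- typed accessors -----------------------------------------------------

    def require(self, obj: dict, key: str, path: str, types: tuple = ()) -> Any:
        """Fetch a required key, recording a finding when absent or mistyped."""
        if key not in obj:
            self.add("required-missing", f"{path}/{key}", f"required key {key!r} missing")
            return None
        value = obj[key]
        if types and not isinstance(value, types):
            self.add(
                "type-mismatch",
                f"{path}/{key}",
                f"{key!r} must be {' or '.join(t.__name__ for t in types)}",
            )
            return None
        return value

    def optional(self, obj: dict, key: str, path: str, types: tuple) -> Any:
        if key not in obj or obj[key] is None:
            return None
        value = obj[key]
        if not isinstance(value, types):
            self.add(
                "type-mismatch",
                f"{path}/{key}",
                f"{key!r} must be {' or '.join(t.__name__ for t in types)}",
            )
            return None
        return value


_SCALARS = (bool, int, float, str)


def _check_accession(col: _Collector, acc: Any, path: str) -> None:
    if isinstance(acc, str) and not ACCESSION_PATTERN.match(acc):
        col.add("bad-accession", path, f"accession {acc!r} does not match PREFIX:digits")


def _check_cv_param(col: _Collector, obj: Any, path: str) -> None:
    if not isinstance(obj, dict):
        col.add("type-mismatch", path, "CV parameter must be an object")
        return
    acc = col.require(obj, "accession", path, (str,))
    col.require(obj, "name", path, (str,))
    _check_accession(col, acc, f"{path}/accession")


def _check_metric_value(col: _Collector, value: Any, path: str) -> None:
    if value is None:
        col.add("bad-value", path, "metric value must not be null")
    elif isinstance(value, _SCALARS):
        pass
    elif isinstance(value, list):
        if not value:
            col.add("bad-value", path, "tuple value must be non-empty")
        elif not all(isinstance(v, _SCALARS) for v in value):
            col.add("bad-value", path, "tuple elements must be scalars")
    elif isinstance(value, dict):
        if not value:
            col.add("bad-value", path, "table value must have at least one column")
            return
        lengths = set()
        for name, cells in value.items():
            if not isinstance(cells, list):
                col.add("bad-value", f"{path}/{name}", "table column must be a list")
                return
            lengths.add(len(cells))
        if len(lengths) > 1:
            col.add("ragged-table", path, "table columns have unequal lengths")
        elif lengths == {0}:
            col.add("bad-value", path, "table columns must be non-empty")
    else:
        col.add("bad-value", path, "value must be a scalar, tuple, or table")


def _check_metric(col: _Collector, obj: Any, path: str) -> Optional[str]:
    if not isinstance(obj, dict):
        col.add("type-mismatch", path, "quality metric must be an object")
        return None
    acc = col.require(obj, "accession", path, (str,))
    col.require(obj, "name", path, (str,))
    _check_accession(col, acc, f"{path}/accession")
    if "value" not in obj:
        col.add("required-missing", f"{path}/value", "metric value missing")
    else:
        _check_metric_value(col, obj["value"], f"{path}/value")
    return acc if isinstance(acc, str) else None


def _check_metadata(col: _Collector, obj: Any, path: str) -> None:
    if not isinstance(obj, dict):
        col.add("type-mismatch", path, "metadata must be an object")
        return
    files = col.require(obj, "inputFiles", path, (list,))
    if files is not None:
        if not files:
            col.add("empty-list", f"{path}/inputFiles", "inputFiles must be non-empty")
        for i, f in enumerate(files):
            fpath = f"{path}/inputFiles/{i}"
            if not isinstance(f, dict):
                col.add("type-mismatch", fpath, "input file must be an object")
                continue
            col.require(f, "name", fpath, (str,))
            col.require(f, "location", fpath, (str,))
            if "fileFormat" in f and f["fileFormat"] is not None:
                _check_cv_param(col, f["fileFormat"], f"{fpath}/fileFormat")
    software = col.require(obj, "analysisSoftware", path, (list,))
    if software is not None:
        if not software:
            col.add(
                "empty-list", f"{path}/analysisSoftware", "analysisSoftware must be non-empty"
            )
        for i, s in enumerate(software):
            spath = f"{path}/analysisSoftware/{i}"
            if not isinstance(s, dict):
                col.add("type-mismatch", spath, "software reference must be an object")
                continue
            acc = col.require(s, "accession", spath, (str,))
            col.require(s, "name", spath, (str,))
            col.require(s, "version", spath, (str,))
            _check_accession(col, acc, f"{spath}/accession")


def _check_element(col: _Collector, obj: Any, path: str) -> None:
    if not isinstance(obj, dict):
        col.add("type-mismatch", path, "quality element must be an object")
        return
    md = col.require(obj, "metadata", path)
    if md is not None:
        _check_metadata(col, md, f"{path}/metadata")
    metrics = col.require(obj, "qualityMetrics", path, (list,))
    if metrics is not None:
        if not metrics:
            col.add("empty-metrics", f"{path}/qualityMetrics", "element carries no metrics")
        seen: set[str] = set()
        for i, m in enumerate(metrics):
            acc = _check_metric(col, m, f"{path}/qualityMetrics/{i}")
            if acc is not None:
                if acc in seen:
                    col.add(
                        "duplicate-metric",
                        f"{path}/qualityMetrics/{i}",
                        f"metric accession {acc!r} repeated within element",
                    )
                seen.add(acc)


def validate_syntax(text: str) -> ValidationReport:
    """Check mzQC text against the format's structural rules.

    Never raises: every problem, including unparseable JSON, becomes a
    finding. Identical input yields an identical report.
    """
    col = _Collector()
    try:
        root = json.loads(text)
    except (json.JSONDecodeError, TypeError) as exc:
        col.add("not-json", "mzQC", f"input is not valid JSON: {exc}")
        return ValidationReport(col.findings)
    if not isinstance(root, dict) or "mzQC" not in root:
        col.add("missing-root", "mzQC", 'document has no "mzQC" root key')
        return ValidationReport(col.findings)
    body = root["mzQC"]
    if not isinstance(body, dict):
        col.add("type-mismatch", "mzQC", "mzQC root must be an object")
        return ValidationReport(col.findings)

    version = col.require(body, "version", "mzQC", (str,))
    if isinstance(version, str) and not VERSION_PATTERN.match(version):
        col.add("bad-version", "mzQC/version", f"malformed version {version!r}")
    stamp = col.require(body, "creationDate", "mzQC", (str,))
    if isinstance(stamp, str) and not TIMESTAMP_PATTERN.match(stamp):
        col.add("bad-timestamp", "mzQC/creationDate", f"malformed timestamp {stamp!r}")

    cvs = col.require(body, "controlledVocabularies", "mzQC", (list,))
    if cvs is not None:
        if not cvs:
            col.add(
                "empty-list",
                "mzQC/controlledVocabularies",
                "controlledVocabularies must be non-empty",
            )
        for i, ref in enumerate(cvs):
            rpath = f"mzQC/controlledVocabularies/{i}"
            if not isinstance(ref, dict):
                col.add("type-mismatch", rpath, "CV reference must be an object")
                continue
            col.require(ref, "name", rpath, (str,))
            col.require(ref, "uri", rpath, (str,))

    runs = col.optional(body, "runQualities", "mzQC", (list,))
    sets = col.optional(body, "setQualities", "mzQC", (list,))
    if not runs and not sets:
        col.add(
            "no-quality-elements",
            "mzQC",
            "document must hold at least one runQuality or setQuality",
        )
    for i, elem in enumerate(runs or []):
        _check_element(col, elem, f"mzQC/runQualities/{i}")
    for i, elem in enumerate(sets or []):
        _check_element(col, elem, f"mzQC/setQualities/{i}")
    return ValidationReport(col.findings)
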