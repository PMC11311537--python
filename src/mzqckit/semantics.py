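"""Semantic validation of mzQC documents against a controlled vocabulary.

Where syntactic validation checks document *structure*, semantic validation
checks that its content makes sense against a CV: every accession used in
the document must resolve to a term, the document's name for a term should
match the CV's, and a metric's value shape (scalar/tuple/table, including
required table columns) must match the shape the term declares. Problems are
reported as findings, never exceptions, reusing the report types of the
syntactic validator.

Severities follow the principle that the accession is the identity carrier:
an unresolvable accession or a wrongly shaped value is an error, while a
divergent display name or the use of an obsolete term is a warning.

Rule ids: ``unknown-accession`` (error), ``name-mismatch`` (warning),
``value-type-mismatch`` (error), ``obsolete-term`` (warning),
``duplicate-metric`` (error), ``duplicate-input-file`` (error),
``unlisted-cv-prefix`` (warning).
"""

from __future__ import annotations

from typing import Optional

from .cv import CvStore, lookup
from .model import CvParam, MzQcDocument, QualityMetric
from .validation import ERROR, WARNING, ValidationFinding, ValidationReport

__all__ = ["validate_semantics"]


def _finding(rule: str, sev: str, path: str, message: str) -> ValidationFinding:
    return ValidationFinding(rule, sev, path, message)


class _SemanticChecker:
    def __init__(self, store: CvStore, cv_refs: list) -> None:
        self.store = store
        self.findings: list[ValidationFinding] = []
        self.cv_refs = cv_refs
        self.seen_prefixes: set[str] = set()

    def check_accession(self, accession: str, name: Optional[str], path: str):
        """Resolve one accession; returns the term or None."""
        prefix = accession.split(":", 1)[0]
        if prefix not in self.seen_prefixes:
            self.seen_prefixes.add(prefix)
            if not self._prefix_listed(prefix):
                self.findings.append(
                    _finding(
                        "unlisted-cv-prefix",
                        WARNING,
                        path,
                        f"CV prefix {prefix!r} has no matching entry in "
                        "controlledVocabularies",
                    )
                )
        term = lookup(self.store, accession)
        if term is None:
            self.findings.append(
                _finding(
                    "unknown-accession",
                    ERROR,
                    path,
                    f"accession {accession!r} does not resolve in the CV",
                )
            )
            return None
        if term.is_obsolete:
            self.findings.append(
                _finding(
                    "obsolete-term",
                    WARNING,
                    path,
                    f"term {accession!r} ({term.name}) is obsolete",
                )
            )
        if name is not None and name.strip() != term.name.strip():
            self.findings.append(
                _finding(
                    "name-mismatch",
                    WARNING,
                    path,
                    f"name {name!r} differs from the CV name {term.name!r}",
                )
            )
        return term

    def _prefix_listed(self, prefix: str) -> bool:
        # The format gives CvReference no prefix field; convention: the
        # prefix must occur (case-insensitively) in a listed CV's name or uri.
        needle = prefix.lower()
        for ref in self.cv_refs:
            hay = f"{ref.name} {ref.uri}".lower()
            if needle in hay:
                return True
        return False

    def check_param(self, param: CvParam, path: str) -> None:
        self.check_accession(param.accession, param.name, path)

    def check_metric(self, metric: QualityMetric, path: str) -> None:
        term = self.check_accession(metric.accession, metric.name, path)
        if term is None or term.value_type == "unspecified":
            return
        kind = metric.value.kind
        declared = term.value_type
        if declared in ("scalar-number", "scalar-text"):
            if kind != "scalar":
                self._type_mismatch(path, declared, kind)
            elif declared == "scalar-number" and not _is_number(metric.value.data):
                self._type_mismatch(path, declared, f"scalar {type(metric.value.data).__name__}")
            elif declared == "scalar-text" and not isinstance(metric.value.data, str):
                self._type_mismatch(path, declared, f"scalar {type(metric.value.data).__name__}")
        elif declared == "tuple":
            if kind != "tuple":
                self._type_mismatch(path, declared, kind)
        elif declared == "table":
            if kind != "table":
                self._type_mismatch(path, declared, kind)
            elif term.table_columns:
                missing = [c for c in term.table_columns if c not in metric.value.data]
                if missing:
                    self.findings.append(
                        _finding(
                            "value-type-mismatch",
                            ERROR,
                            path,
                            f"table value lacks required column(s) {missing}",
                        )
                    )

    def _type_mismatch(self, path: str, declared: str, actual: str) -> None:
        self.findings.append(
            _finding(
                "value-type-mismatch",
                ERROR,
                path,
                f"CV declares value type {declared!r} but the value is {actual}",
            )
        )


def _is_number(value) -> bool:
    # booleans are not acceptable where the CV declares a number
    return isinstance(value, (int, float)) and not isinstance(value, bool)


def validate_semantics(doc: MzQcDocument, store: CvStore) -> ValidationReport:
    """Check a document's CV-anchored content against ``store``.

    The document is expected to have passed syntactic validation; this
    function still tolerates structural oddities (it walks whatever is
    present) and reports findings only.
    """
    checker = _SemanticChecker(store, doc.controlledVocabularies)
    for path, elem in doc.all_elements():
        md = elem.metadata
        seen_files: set[str] = set()
        for i, f in enumerate(md.inputFiles):
            fpath = f"{path}/metadata/inputFiles/{i}"
            if f.name in seen_files:
                checker.findings.append(
                    _finding(
                        "duplicate-input-file",
                        ERROR,
                        fpath,
                        f"input file name {f.name!r} repeated within element",
                    )
                )
            seen_files.add(f.name)
            if f.fileFormat is not None:
                checker.check_param(f.fileFormat, f"{fpath}/fileFormat")
            for j, prop in enumerate(f.fileProperties or []):
                checker.check_param(prop, f"{fpath}/fileProperties/{j}")
        for i, sw in enumerate(md.analysisSoftware):
            checker.check_accession(
                sw.accession, sw.name, f"{path}/metadata/analysisSoftware/{i}"
            )
        for i, param in enumerate(md.cvParameters or []):
            checker.check_param(param, f"{path}/metadata/cvParameters/{i}")
        seen_metrics: set[str] = set()
        for i, metric in enumerate(elem.qualityMetrics):
            mpath = f"{path}/qualityMetrics/{i}"
            if metric.accession in seen_metrics:
                checker.findings.append(
                    _finding(
                        "duplicate-metric",
                        ERROR,
                        mpath,
                        f"metric accession {metric.accession!r} repeated within element",
                    )
                )
            seen_metrics.add(metric.accession)
            checker.check_metric(metric, mpath)
    return ValidationReport(checker.findings)
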