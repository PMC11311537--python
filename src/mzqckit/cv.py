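"""Controlled-vocabulary support: OBO parsing and term queries.

Every mzQC metric is anchored to a controlled-vocabulary term by accession;
semantic validation needs to resolve those accessions, compare names, and
check declared value shapes. This module parses a CV supplied as a local
OBO flat file (offline-first — the real PSI-MS CV can be dropped in by the
user, and the package's synthetic toy CV serves the test suite) and answers
term queries.

Only ``[Term]`` stanzas are interpreted; ``[Typedef]`` and other stanzas are
skipped. Value-shape declarations are read from ``xref: value-type:...``
lines, and required table columns from ``xref: table-columns:a,b`` lines;
terms without a declaration get the shape ``unspecified`` and are exempt
from value-type checking.
"""

from __future__ import annotations

import logging
import os
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Union

__all__ = [
    "CvError",
    "CvTerm",
    "CvStore",
    "load_obo",
    "load_obo_file",
    "lookup",
    "is_descendant",
    "VALUE_TYPES",
]

logger = logging.getLogger(__name__)

#: Declared value shapes a term may carry.
VALUE_TYPES = ("scalar-number", "scalar-text", "tuple", "table", "unspecified")


class CvError(ValueError):
    """Raised for unparseable OBO input or unresolvable accessions."""


@dataclass
class CvTerm:
    accession: str
    name: str
    definition: Optional[str] = None
    parents: list[str] = field(default_factory=list)
    value_type: str = "unspecified"
    table_columns: Optional[list[str]] = None
    is_obsolete: bool = False


@dataclass
class CvStore:
    """A parsed controlled vocabulary with accession-keyed term lookup."""

    terms: dict[str, CvTerm] = field(default_factory=dict)
    source_name: Optional[str] = None
    source_version: Optional[str] = None

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    @property
    def dangling_parents(self) -> set[str]:
        """Parent accessions referenced but not defined in this store."""
        return {
            parent
            for term in self.terms.values()
            for parent in term.parents
            if parent not in self.terms
        }

    @property
    def prefixes(self) -> set[str]:
        return {acc.split(":", 1)[0] for acc in self.terms}


def _unquote_def(value: str) -> str:
    # def lines look like: def: "text" [citations]
    if value.startswith('"'):
        end = value.find('"', 1)
        if end > 0:
            return value[1:end]
    return value


def load_obo(text: str) -> CvStore:
    """Parse OBO 1.2/1.4 flat-file text into a :class:`CvStore`.

    Raises :class:`CvError` with a line number for a ``[Term]`` stanza
    lacking an ``id:`` line, and for duplicate term ids.
    """
    store = CvStore()
    current: Optional[dict] = None
    current_line = 0
    in_term = False
    in_header = True

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        if "id" not in current:
            raise CvError(f"line {current_line}: [Term] stanza without an id")
        acc = current["id"]
        if acc in store.terms:
            raise CvError(f"line {current_line}: duplicate term id {acc!r}")
        store.terms[acc] = CvTerm(
            accession=acc,
            name=current.get("name", ""),
            definition=current.get("def"),
            parents=current.get("is_a", []),
            value_type=current.get("value_type", "unspecified"),
            table_columns=current.get("table_columns"),
            is_obsolete=current.get("is_obsolete", False),
        )
        current = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip() if not raw.strip().startswith("!") else ""
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_header = False
            in_term = line == "[Term]"
            if in_term:
                current = {}
                current_line = lineno
            elif line != "[Typedef]":
                logger.debug("skipping stanza %s at line %d", line, lineno)
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if in_header:
            if tag == "ontology":
                store.source_name = value
            elif tag == "data-version":
                store.source_version = value
            continue
        if not in_term or current is None:
            continue
        if tag == "id":
            if "id" in current:
                raise CvError(f"line {lineno}: repeated id in one stanza")
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "def":
            current["def"] = _unquote_def(value)
        elif tag == "is_a":
            current.setdefault("is_a", []).append(value.split()[0])
        elif tag == "is_obsolete":
            current["is_obsolete"] = value.lower() == "true"
        elif tag == "xref":
            if value.startswith("value-type:"):
                declared = value.split(":", 1)[1].strip()
                if declared not in VALUE_TYPES:
                    raise CvError(f"line {lineno}: unknown value type {declared!r}")
                current["value_type"] = declared
            elif value.startswith("table-columns:"):
                cols = value.split(":", 1)[1].strip()
                current["table_columns"] = [c.strip() for c in cols.split(",") if c.strip()]
    flush()
    return store


def load_obo_file(path: Union[str, os.PathLike]) -> CvStore:
    with open(path, "r", encoding="utf-8") as handle:
        return load_obo(handle.read())


def lookup(store: CvStore, accession: str) -> Optional[CvTerm]:
    """Exact-match term lookup; ``None`` for unknown accessions."""
    return store.terms.get(accession)


def is_descendant(store: CvStore, accession: str, ancestor: str) -> bool:
    """True iff ``ancestor`` is reachable from ``accession`` via ``is_a``.

    Reflexive: every term is its own descendant. Both accessions must
    resolve in the store; an ``is_a`` cycle is reported as an error rather
    than looping.
    """
    if accession not in store.terms:
        raise CvError(f"unknown accession {accession!r}")
    if ancestor not in store.terms:
        raise CvError(f"unknown accession {ancestor!r}")
    seen: set[str] = set()
    queue: deque[str] = deque([accession])
    while queue:
        acc = queue.popleft()
        if acc == ancestor:
            return True
        if acc in seen:
            continue
        seen.add(acc)
        term = store.terms.get(acc)
        if term is None:  # dangling parent: cannot continue upward
            continue
        queue.extend(p for p in term.parents if p not in seen)
    return False


def assert_acyclic(store: CvStore) -> None:
    """Raise :class:`CvError` if the ``is_a`` graph contains a cycle."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {acc: WHITE for acc in store.terms}

    for root in store.terms:
        if color[root] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(root, 0)]
        color[root] = GRAY
        while stack:
            node, idx = stack[-1]
            parents = [p for p in store.terms[node].parents if p in store.terms]
            if idx < len(parents):
                stack[-1] = (node, idx + 1)
                nxt = parents[idx]
                if color[nxt] == GRAY:
                    raise CvError(f"is_a cycle involving {nxt!r}")
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, 0))
            else:
                color[node] = BLACK
                stack.pop()
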