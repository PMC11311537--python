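"""OBO parsing and is_a reachability queries."""

import io

import networkx as nx
import numpy as np
import obonet
import pytest

from mzqckit.cv import CvError, assert_acyclic, is_descendant, load_obo, lookup
from mzqckit.registry import METRICS, ROOT_TERM
from mzqckit.synthetic import toy_obo


def test_single_stanza():
    store = load_obo("[Term]\nid: QCX:0000001\nname: toy metric count\n")
    assert len(store) == 1
    assert lookup(store, "QCX:0000001").name == "toy metric count"


def test_is_a_captured():
    store = load_obo(
        "[Term]\nid: QCX:0000001\nname: child\nis_a: QCX:0000000 ! parent comment\n"
    )
    assert lookup(store, "QCX:0000001").parents == ["QCX:0000000"]
    assert "QCX:0000000" in store.dangling_parents


def test_missing_id_reports_stanza_line():
    text = "[Term]\nid: QCX:1\nname: ok\n\n[Term]\nname: no id here\n"
    with pytest.raises(CvError, match="line 5"):
        load_obo(text)


def test_duplicate_id_rejected():
    text = "[Term]\nid: QCX:1\nname: a\n\n[Term]\nid: QCX:1\nname: b\n"
    with pytest.raises(CvError, match="duplicate"):
        load_obo(text)


def test_typedef_stanzas_skipped():
    text = "[Typedef]\nid: part_of\nname: part of\n\n[Term]\nid: QCX:1\nname: a\n"
    assert list(load_obo(text).terms) == ["QCX:1"]


def test_toy_cv_contents(toy_store):
    tic = lookup(toy_store, METRICS["tic"].accession)
    assert tic.name == "total ion chromatogram"
    assert tic.value_type == "table"
    assert tic.table_columns == ["rt_seconds", "intensity"]
    assert tic.parents == [ROOT_TERM.accession]
    assert lookup(toy_store, "QCX:9000009").is_obsolete
    assert lookup(toy_store, "QCX:4999999") is None
    assert_acyclic(toy_store)
    assert toy_store.source_name == "qcx"
    assert toy_store.source_version == "0.1.0"


def test_stanza_order_insensitive(toy_store):
    stanzas = toy_obo().split("\n\n")
    header, terms = stanzas[0], stanzas[1:]
    shuffled = "\n\n".join([header] + terms[::-1])
    store2 = load_obo(shuffled)
    assert set(store2.terms) == set(toy_store.terms)
    for acc, term in toy_store.terms.items():
        assert store2.terms[acc] == term


class TestIsDescendant:
    def test_direct_parent(self, toy_store):
        assert is_descendant(toy_store, METRICS["tic"].accession, ROOT_TERM.accession)

    def test_reflexive(self, toy_store):
        acc = METRICS["tic"].accession
        assert is_descendant(toy_store, acc, acc)

    def test_not_ancestor(self, toy_store):
        assert not is_descendant(
            toy_store, ROOT_TERM.accession, METRICS["tic"].accession
        )

    def test_unknown_accession_errors(self, toy_store):
        with pytest.raises(CvError, match="unknown accession"):
            is_descendant(toy_store, "QCX:4999999", ROOT_TERM.accession)

    def test_random_dag_matches_graph_oracle(self):
        """All-pairs reachability equals an obonet/networkx oracle."""
        rng = np.random.default_rng(1234)
        n = 10
        accs = [f"QCX:{i + 1:07d}" for i in range(n)]
        stanzas = ["format-version: 1.2\nontology: chain"]
        for i, acc in enumerate(accs):
            lines = [f"[Term]", f"id: {acc}", f"name: term {i}"]
            # parents only among earlier terms: guarantees a DAG
            for j in range(i):
                if rng.random() < 0.3:
                    lines.append(f"is_a: {accs[j]}")
            stanzas.append("\n".join(lines))
        text = "\n\n".join(stanzas) + "\n"

        store = load_obo(text)
        graph = obonet.read_obo(io.StringIO(text))
        for a in accs:
            for b in accs:
                expected = a == b or (
                    graph.has_node(a) and graph.has_node(b) and nx.has_path(graph, a, b)
                )
                assert is_descendant(store, a, b) == expected, (a, b)

    def test_cycle_detected_not_looped(self):
        text = (
            "[Term]\nid: QCX:1\nname: a\nis_a: QCX:2\n\n"
            "[Term]\nid: QCX:2\nname: b\nis_a: QCX:1\n"
        )
        store = load_obo(text)
        with pytest.raises(CvError, match="cycle"):
            assert_acyclic(store)
        # reachability queries still terminate on the cyclic store
        assert is_descendant(store, "QCX:1", "QCX:2")
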