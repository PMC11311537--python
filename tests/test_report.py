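"""Merging, percentile ranking, clustering, and report rendering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzqckit.model import QualityMetric
from mzqckit.report import (
    MergeError,
    MetricMatrix,
    MetricSelector,
    build_metric_matrix,
    cluster_order,
    merge_documents,
    percentile_rank,
    percentile_rank_matrix,
    render_report,
)
from mzqckit.registry import METRICS
from mzqckit.synthetic import run_metadata
from mzqckit.model import MzQcDocument, QualityElement
from mzqckit.synthetic import toy_cv_reference
from mzqckit.workflow import default_metric_selection, partial_documents


def _doc(elements):
    return MzQcDocument(
        version="1.0.0",
        creationDate="2024-02-20T12:00:00",
        controlledVocabularies=[toy_cv_reference()],
        runQualities=elements,
    )


def _elem(run, accessions_values):
    return QualityElement(
        metadata=run_metadata(run),
        qualityMetrics=[
            QualityMetric(accession=a, name=f"m {a}", value=v)
            for a, v in accessions_values
        ],
    )


class TestMerge:
    def test_single_document_identity(self):
        doc = _doc([_elem("r1", [("QCX:1", 5)])])
        merged = merge_documents([doc])
        merged.creationDate = doc.creationDate
        assert merged == doc

    def test_disjoint_metrics_unioned(self):
        a = _doc([_elem("r1", [("QCX:1", 5)])])
        b = _doc([_elem("r1", [("QCX:2", 6)])])
        merged = merge_documents([a, b])
        assert len(merged.runQualities) == 1
        accs = [m.accession for m in merged.runQualities[0].qualityMetrics]
        assert accs == ["QCX:1", "QCX:2"]

    def test_equal_values_idempotent(self):
        a = _doc([_elem("r1", [("QCX:1", 5)])])
        b = _doc([_elem("r1", [("QCX:1", 5)])])
        merged = merge_documents([a, b])
        assert len(merged.runQualities[0].qualityMetrics) == 1

    def test_conflict_is_error_naming_run_and_accession(self):
        a = _doc([_elem("r1", [("QCX:1", 5)])])
        b = _doc([_elem("r1", [("QCX:1", 6)])])
        with pytest.raises(MergeError, match=r"r1.*QCX:1"):
            merge_documents([a, b])

    def test_conflict_keep_first(self):
        a = _doc([_elem("r1", [("QCX:1", 5)])])
        b = _doc([_elem("r1", [("QCX:1", 6)])])
        merged = merge_documents([a, b], on_conflict="keep-first")
        assert merged.runQualities[0].qualityMetrics[0].value.data == 5

    def test_merge_idempotent_and_order_insensitive(self):
        a = _doc([_elem("r1", [("QCX:1", 5)]), _elem("r2", [("QCX:1", 7)])])
        b = _doc([_elem("r2", [("QCX:2", 1)])])
        once = merge_documents([a, b])
        twice = merge_documents([once])
        twice.creationDate = once.creationDate
        assert twice == once
        flipped = merge_documents([b, a])
        runs = lambda d: {
            e.metadata.inputFiles[0].location: {
                m.accession: m.value.data for m in e.qualityMetrics
            }
            for e in d.runQualities
        }
        assert runs(flipped) == runs(once)

    def test_cv_references_deduplicated(self):
        a = _doc([_elem("r1", [("QCX:1", 5)])])
        b = _doc([_elem("r2", [("QCX:1", 6)])])
        merged = merge_documents([a, b])
        assert len(merged.controlledVocabularies) == 1

    def test_workflow_partials_cover_all_runs(self, small_experiment):
        spec, runs, psm_tables, _ = small_experiment
        docs = partial_documents(runs, psm_tables, spec.q_threshold)
        merged = merge_documents(list(docs.values()))
        assert len(merged.runQualities) == len(runs)
        expected = set()
        for doc in docs.values():
            for elem in doc.runQualities:
                expected |= {m.accession for m in elem.qualityMetrics}
        for elem in merged.runQualities:
            assert {m.accession for m in elem.qualityMetrics} == expected


class TestMetricMatrix:
    def test_full_grid(self, small_experiment):
        spec, runs, psm_tables, _ = small_experiment
        merged = merge_documents(list(partial_documents(runs, psm_tables).values()))
        matrix = build_metric_matrix(merged, default_metric_selection())
        assert matrix.values.shape == (len(default_metric_selection()), len(runs))
        assert not matrix.values.isna().any().any()

    def test_missing_cell_where_metric_absent(self):
        doc = _doc(
            [_elem("r1", [("QCX:1", 5), ("QCX:2", 2)]), _elem("r2", [("QCX:1", 7)])]
        )
        matrix = build_metric_matrix(
            doc, [MetricSelector("QCX:1"), MetricSelector("QCX:2")]
        )
        assert matrix.values.isna().sum().sum() == 1
        assert math.isnan(matrix.values.loc["QCX:2", "r2"])

    def test_unknown_accession_rejected(self):
        doc = _doc([_elem("r1", [("QCX:1", 5)])])
        with pytest.raises(MergeError, match="QCX:999"):
            build_metric_matrix(doc, [MetricSelector("QCX:999")])

    def test_tic_sum_matches_generator_total(self, small_experiment):
        spec, runs, psm_tables, truth = small_experiment
        merged = merge_documents(list(partial_documents(runs, psm_tables).values()))
        sel = MetricSelector(
            METRICS["tic"].accession, reduce=("sum", "intensity"), label="tic"
        )
        matrix = build_metric_matrix(merged, [sel])
        for run in runs:
            expected = math.fsum(truth[run.run_name].tic)
            assert matrix.values.loc["tic", run.run_name] == pytest.approx(
                expected, rel=1e-9
            )


def _rank_oracle(values):
    out = []
    clean = [v for v in values if not math.isnan(v)]
    for v in values:
        if math.isnan(v):
            out.append(float("nan"))
        else:
            below = sum(1 for w in clean if w < v)
            ties = sum(1 for w in clean if w == v)
            out.append(100.0 * (below + 0.5 * ties) / len(clean))
    return out


class TestPercentileRank:
    def test_counting_example(self):
        assert percentile_rank([10, 20, 30, 40]).tolist() == [12.5, 37.5, 62.5, 87.5]

    def test_all_ties(self):
        assert percentile_rank([5, 5, 5, 5]).tolist() == [50.0, 50.0, 50.0, 50.0]

    def test_single_value(self):
        assert percentile_rank([7.0]).tolist() == [50.0]

    def test_all_missing_rejected(self):
        with pytest.raises(MergeError):
            percentile_rank([float("nan")])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.one_of(st.integers(min_value=0, max_value=5).map(float), st.just(float("nan"))),
            min_size=1,
            max_size=20,
        )
    )
    def test_matches_counting_oracle(self, values):
        if all(math.isnan(v) for v in values):
            return
        got = percentile_rank(values)
        want = _rank_oracle(values)
        assert np.allclose(got, want, equal_nan=True)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        assert np.allclose(percentile_rank(x), percentile_rank(np.exp(x)))

    def test_mean_rank_is_fifty_for_tie_free(self):
        x = np.arange(17, dtype=float)
        assert percentile_rank(x).mean() == pytest.approx(50.0)

    def test_bounds_open_interval(self):
        r = percentile_rank(np.arange(100, dtype=float))
        assert (r > 0).all() and (r < 100).all()


class TestClusterOrder:
    def _matrix(self, data, runs, metrics):
        return MetricMatrix(values=pd.DataFrame(data, index=metrics, columns=runs))

    def test_identical_columns_adjacent(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 100, size=(5, 3))
        data = np.column_stack([base, base[:, 0]])
        m = self._matrix(data, ["r1", "r2", "r3", "r4"], [f"m{i}" for i in range(5)])
        orders = cluster_order(m)
        i, j = orders.run_order.index("r1"), orders.run_order.index("r4")
        assert abs(i - j) == 1

    def test_two_blocks_stay_together(self):
        lo = np.full((4, 2), 10.0) + np.arange(4)[:, None]
        hi = np.full((4, 2), 90.0) + np.arange(4)[:, None]
        data = np.column_stack([lo[:, 0], hi[:, 0], lo[:, 1] + 0.5, hi[:, 1] + 0.5])
        m = self._matrix(data, ["a_lo", "b_hi", "c_lo", "d_hi"], [f"m{i}" for i in range(4)])
        orders = cluster_order(m)
        pos = {r: i for i, r in enumerate(orders.run_order)}
        assert abs(pos["a_lo"] - pos["c_lo"]) == 1
        assert abs(pos["b_hi"] - pos["d_hi"]) == 1

    def test_input_column_order_irrelevant(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 100, size=(6, 5))
        runs = [f"r{i}" for i in range(5)]
        m1 = self._matrix(data, runs, [f"m{i}" for i in range(6)])
        perm = [3, 0, 4, 1, 2]
        m2 = MetricMatrix(values=m1.values.iloc[:, perm])
        o1, o2 = cluster_order(m1), cluster_order(m2)
        assert o1.run_order == o2.run_order
        assert np.allclose(o1.run_linkage, o2.run_linkage)

    def test_linkage_heights_match_distance_oracle(self):
        # two leaves merge at exactly their Euclidean distance
        data = np.array([[0.0, 3.0], [0.0, 4.0]])
        m = self._matrix(data, ["r1", "r2"], ["m1", "m2"])
        orders = cluster_order(m)
        assert orders.run_linkage[0, 2] == pytest.approx(5.0)

    def test_no_overlap_pair_rejected(self):
        nan = float("nan")
        data = [[1.0, nan], [nan, 2.0]]
        m = self._matrix(data, ["r1", "r2"], ["m1", "m2"])
        with pytest.raises(MergeError, match="no overlapping"):
            cluster_order(m)

    def test_too_small_rejected(self):
        m = self._matrix([[1.0, 2.0]], ["r1", "r2"], ["m1"])
        with pytest.raises(MergeError, match="at least 2"):
            cluster_order(m)


class TestRenderReport:
    def test_files_written_and_tsv_roundtrip(self, tmp_path, small_experiment):
        spec, runs, psm_tables, _ = small_experiment
        merged = merge_documents(list(partial_documents(runs, psm_tables).values()))
        groups = {r.run_name: spec.condition_of(r.run_name) for r in runs}
        matrix = build_metric_matrix(merged, default_metric_selection(), groups=groups)
        ranked = percentile_rank_matrix(matrix)
        orders = cluster_order(ranked)
        paths = render_report(ranked, orders, tmp_path / "report")
        assert (tmp_path / "report.png").stat().st_size > 0
        frame = pd.read_csv(paths["tsv"], sep="\t", index_col="metric")
        assert list(frame.index) == orders.metric_order
        assert list(frame.columns) == orders.run_order
        expected = ranked.values.loc[orders.metric_order, orders.run_order]
        assert np.allclose(frame.to_numpy(), expected.to_numpy())

    def test_unwritable_path_is_io_error(self, tmp_path, small_experiment):
        spec, runs, psm_tables, _ = small_experiment
        merged = merge_documents(list(partial_documents(runs, psm_tables).values()))
        ranked = percentile_rank_matrix(
            build_metric_matrix(merged, default_metric_selection())
        )
        orders = cluster_order(ranked)
        with pytest.raises(OSError):
            render_report(ranked, orders, tmp_path / "nosuchdir" / "report")
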