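"""Merging partial mzQC reports and rendering the clustered QC heatmap.

A QC workflow often produces several partial mzQC files per experiment —
e.g. one per metric-computing tool. :func:`merge_documents` coalesces them
into one report, joining runQuality elements that describe the same run
(matched by the location of their first input file, falling back to its
name) and taking the union of their metrics.

For visual inspection the merged report is turned into a runs x metrics
matrix, each metric is percentile-rank scaled across runs (mean-rank
convention, so ties share their average position on a 0-100 scale), both
axes are ordered by agglomerative hierarchical clustering (average linkage,
Euclidean distance over pairwise-complete entries), and the result is drawn
as a grayscale heatmap with dendrograms — darker cells mean lower
percentile ranks. Percentile ranking is applied per metric across runs,
never across metrics, since different metrics carry incomparable units.
"""

from __future__ import annotations

import datetime
import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from .model import (
    CvReference,
    Metadata,
    MetricValue,
    MzQcDocument,
    QualityElement,
)

__all__ = [
    "MergeError",
    "merge_documents",
    "MetricSelector",
    "MetricMatrix",
    "build_metric_matrix",
    "percentile_rank",
    "percentile_rank_matrix",
    "ClusterResult",
    "cluster_order",
    "render_report",
]

logger = logging.getLogger(__name__)


class MergeError(ValueError):
    pass


def _now_iso() -> str:
    return datetime.datetime.now().strftime("%Y-%m-%dT%H:%M:%S")


def _run_key(elem: QualityElement) -> str:
    f = elem.metadata.inputFiles[0]
    return f.location or f.name


def _values_equal(a: MetricValue, b: MetricValue) -> bool:
    return a.kind == b.kind and a.data == b.data


def _merge_elements(target: QualityElement, other: QualityElement, key: str, on_conflict: str) -> None:
    have = {m.accession: m for m in target.qualityMetrics}
    for metric in other.qualityMetrics:
        existing = have.get(metric.accession)
        if existing is None:
            target.qualityMetrics.append(metric)
            have[metric.accession] = metric
        elif not _values_equal(existing.value, metric.value):
            if on_conflict == "keep-first":
                logger.warning(
                    "metric conflict for run %s, accession %s: keeping first value",
                    key,
                    metric.accession,
                )
            else:
                raise MergeError(
                    f"metric conflict for run {key!r}, accession {metric.accession!r}"
                )
    # union provenance
    seen_files = {f.name for f in target.metadata.inputFiles}
    for f in other.metadata.inputFiles:
        if f.name not in seen_files:
            target.metadata.inputFiles.append(f)
            seen_files.add(f.name)
    seen_sw = {(s.accession, s.name, s.version) for s in target.metadata.analysisSoftware}
    for s in other.metadata.analysisSoftware:
        if (s.accession, s.name, s.version) not in seen_sw:
            target.metadata.analysisSoftware.append(s)
            seen_sw.add((s.accession, s.name, s.version))
    if target.metadata.label is None:
        target.metadata.label = other.metadata.label


def _copy_element(elem: QualityElement) -> QualityElement:
    return QualityElement(
        metadata=Metadata(
            inputFiles=list(elem.metadata.inputFiles),
            analysisSoftware=list(elem.metadata.analysisSoftware),
            label=elem.metadata.label,
            cvParameters=elem.metadata.cvParameters,
            extras=dict(elem.metadata.extras),
        ),
        qualityMetrics=list(elem.qualityMetrics),
        kind=elem.kind,
        extras=dict(elem.extras),
    )


def merge_documents(
    docs: Sequence[MzQcDocument], on_conflict: str = "error"
) -> MzQcDocument:
    """Merge partial mzQC documents into one report.

    runQuality elements describing the same run are coalesced into a single
    element holding the union of their metrics; analysisSoftware lists are
    unioned, controlledVocabularies deduplicated by (name, uri, version),
    setQualities concatenated, and the merged document gets a fresh
    creation timestamp.

    The same metric accession appearing for the same run with unequal
    values is a conflict: an error by default, or keep-first with a logged
    warning when ``on_conflict="keep-first"``.
    """
    if not docs:
        raise MergeError("nothing to merge")
    if on_conflict not in ("error", "keep-first"):
        raise MergeError(f"unknown conflict policy {on_conflict!r}")

    merged_runs: dict[str, QualityElement] = {}
    cv_refs: dict[tuple, CvReference] = {}
    set_qualities: list[QualityElement] = []
    for doc in docs:
        for ref in doc.controlledVocabularies:
            cv_refs.setdefault((ref.name, ref.uri, ref.version), ref)
        for elem in doc.runQualities:
            key = _run_key(elem)
            if key in merged_runs:
                _merge_elements(merged_runs[key], elem, key, on_conflict)
            else:
                merged_runs[key] = _copy_element(elem)
        set_qualities.extend(doc.setQualities)

    merged = MzQcDocument(
        version=docs[0].version,
        creationDate=_now_iso(),
        controlledVocabularies=list(cv_refs.values()),
        runQualities=list(merged_runs.values()),
        setQualities=set_qualities,
        description=docs[0].description,
        contactName=docs[0].contactName,
        contactAddress=docs[0].contactAddress,
    )
    merged.check()
    return merged


# --- metric matrix ----------------------------------------------------------


@dataclass(frozen=True)
class MetricSelector:
    """Names one numeric quantity to pull out of each run's metrics.

    Scalar metrics need no reduction. Tuple and table metrics are reduced to
    one number with ``reduce``:

    - ``("index", i)`` — element ``i`` of a tuple value;
    - ``("span", None)`` — max minus min of a tuple value;
    - ``("sum"|"mean"|"max"|"min", column)`` — reduction of a table column.
    """

    accession: str
    reduce: Optional[tuple[str, Optional[Union[int, str]]]] = None
    label: Optional[str] = None


@dataclass
class MetricMatrix:
    """Runs x metrics numeric grid (stored metrics-as-rows) with labels."""

    values: pd.DataFrame  # index: metric labels; columns: run labels
    group_labels: Optional[dict[str, str]] = None  # run label -> condition

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)

    @property
    def metric_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_labels(self) -> list[str]:
        return list(self.values.columns)


def _element_run_label(elem: QualityElement) -> str:
    if elem.metadata.label:
        return elem.metadata.label
    name = elem.metadata.inputFiles[0].name
    return os.path.splitext(os.path.basename(name))[0]


def _reduce_value(value: MetricValue, selector: MetricSelector) -> float:
    if selector.reduce is None:
        if value.kind != "scalar":
            raise MergeError(
                f"metric {selector.accession} is {value.kind}-valued; a reduction is required"
            )
        return float(value.data)
    op, arg = selector.reduce
    if value.kind == "tuple":
        data = [float(v) for v in value.data]
        if op == "index":
            return data[int(arg)]
        if op == "span":
            return max(data) - min(data)
        if op in ("sum", "mean", "max", "min"):
            return float(getattr(np, op)(data))
        raise MergeError(f"unknown tuple reduction {op!r}")
    if value.kind == "table":
        if arg not in value.data:
            raise MergeError(f"table metric {selector.accession} has no column {arg!r}")
        col = np.asarray(value.data[arg], dtype=float)
        if op in ("sum", "mean", "max", "min"):
            return float(getattr(np, op)(col))
        raise MergeError(f"unknown table reduction {op!r}")
    raise MergeError(f"cannot reduce scalar metric {selector.accession} with {op!r}")


def build_metric_matrix(
    doc: MzQcDocument,
    selection: Sequence[MetricSelector],
    groups: Optional[dict[str, str]] = None,
) -> MetricMatrix:
    """Extract a metrics x runs numeric matrix from a merged document.

    Each selector becomes a row, each runQuality a column; a run lacking a
    selected metric yields a missing cell. A selector whose accession occurs
    in no run at all is an error (it usually indicates a typo).
    """
    runs = [( _element_run_label(e), e) for e in doc.runQualities]
    if not runs:
        raise MergeError("document has no runQualities")
    rows: dict[str, dict[str, float]] = {}
    seen_accessions = {
        m.accession for _, e in runs for m in e.qualityMetrics
    }
    for selector in selection:
        if selector.accession not in seen_accessions:
            raise MergeError(f"no run carries metric {selector.accession!r}")
        label = selector.label or selector.accession
        row: dict[str, float] = {}
        for run_label, elem in runs:
            metric = next(
                (m for m in elem.qualityMetrics if m.accession == selector.accession),
                None,
            )
            row[run_label] = np.nan if metric is None else _reduce_value(metric.value, selector)
        rows[label] = row
    frame = pd.DataFrame(rows).T.reindex(columns=[label for label, _ in runs])
    return MetricMatrix(values=frame, group_labels=groups)


# --- percentile ranking -----------------------------------------------------


def percentile_rank(values: Sequence[float]) -> np.ndarray:
    """Percentile ranks on a 0-100 scale, mean-rank convention.

    ``rank(x) = 100 * (#{v < x} + 0.5 * #{v == x}) / n`` over the n
    non-missing values; missing entries stay missing. Invariant under any
    strictly monotone transform of the inputs; an all-ties vector maps to
    all 50.
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n == 0:
        raise MergeError("cannot percentile-rank an all-missing vector")
    out = np.full(arr.shape, np.nan)
    # average ranks are 1-based; (rank - 0.5)/n reproduces the counting form
    out[mask] = 100.0 * (rankdata(arr[mask], method="average") - 0.5) / n
    return out


def percentile_rank_matrix(matrix: MetricMatrix) -> MetricMatrix:
    """Percentile-rank each metric (row) across runs."""
    ranked = matrix.values.copy()
    for label in ranked.index:
        ranked.loc[label] = percentile_rank(ranked.loc[label].to_numpy())
    return MetricMatrix(values=ranked, group_labels=matrix.group_labels)


# --- clustering -------------------------------------------------------------


@dataclass
class ClusterResult:
    metric_order: list[str]
    run_order: list[str]
    metric_linkage: np.ndarray
    run_linkage: np.ndarray

    def __iter__(self):
        return iter((self.metric_order, self.run_order))


def _pairwise_complete_euclidean(data: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    n = data.shape[0]
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(data[i]) & ~np.isnan(data[j])
            if not mask.any():
                raise MergeError(
                    f"no overlapping values between {labels[i]!r} and {labels[j]!r}"
                )
            diff = data[i, mask] - data[j, mask]
            condensed.append(float(np.sqrt(np.sum(diff**2))))
    return np.asarray(condensed)


def cluster_order(matrix: MetricMatrix, method: str = "average") -> ClusterResult:
    """Order both axes by hierarchical clustering of the ranked matrix.

    Agglomerative clustering (average linkage by default, overridable with
    any scipy linkage method) with Euclidean distance over
    pairwise-complete entries, applied independently to metrics (rows) and
    runs (columns). Labels are pre-sorted so tie-breaking is deterministic;
    the returned leaf orders are reproducible for identical input.
    """
    if len(matrix.metric_labels) < 2 or len(matrix.run_labels) < 2:
        raise MergeError("clustering needs at least 2 metrics and 2 runs")
    frame = matrix.values.sort_index(axis=0).sort_index(axis=1)
    metric_labels = list(frame.index)
    run_labels = list(frame.columns)
    data = frame.to_numpy()
    metric_linkage = hierarchy.linkage(
        _pairwise_complete_euclidean(data, metric_labels), method=method
    )
    run_linkage = hierarchy.linkage(
        _pairwise_complete_euclidean(data.T, run_labels), method=method
    )
    metric_order = [metric_labels[i] for i in hierarchy.leaves_list(metric_linkage)]
    run_order = [run_labels[i] for i in hierarchy.leaves_list(run_linkage)]
    return ClusterResult(metric_order, run_order, metric_linkage, run_linkage)


# --- rendering --------------------------------------------------------------


def render_report(
    matrix: MetricMatrix,
    orders: ClusterResult,
    out_prefix: Union[str, os.PathLike],
    image_format: str = "png",
) -> dict[str, str]:
    """Write the clustered heatmap image and the matrix TSV.

    ``matrix`` should already be percentile-ranked. Writes
    ``<out_prefix>.<image_format>`` (heatmap with dendrograms, optional
    condition color strip, grayscale with darker = lower rank) and
    ``<out_prefix>.tsv`` (the ranked matrix in clustered order, readable
    back with :func:`pandas.read_csv`). Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.values.loc[orders.metric_order, orders.run_order]

    prefix = os.fspath(out_prefix)
    tsv_path = f"{prefix}.tsv"
    img_path = f"{prefix}.{image_format}"
    ordered.to_csv(tsv_path, sep="\t", index_label="metric")

    n_rows, n_cols = ordered.shape
    has_groups = bool(matrix.group_labels)
    fig = plt.figure(figsize=(max(6.0, 0.9 * n_cols + 3), max(5.0, 0.45 * n_rows + 3)))
    gs = fig.add_gridspec(
        3,
        2,
        width_ratios=[1.2, 4],
        height_ratios=[1.2, 0.15 if has_groups else 0.001, 4],
        hspace=0.05,
        wspace=0.05,
    )

    ax_col_dend = fig.add_subplot(gs[0, 1])
    # scipy draws leaves in leaves_list order; suppress labels here
    hierarchy.dendrogram(
        orders.run_linkage, ax=ax_col_dend, no_labels=True, color_threshold=0, link_color_func=lambda _: "black"
    )
    ax_col_dend.axis("off")

    ax_row_dend = fig.add_subplot(gs[2, 0])
    hierarchy.dendrogram(
        orders.metric_linkage,
        ax=ax_row_dend,
        orientation="left",
        no_labels=True,
        color_threshold=0,
        link_color_func=lambda _: "black",
    )
    ax_row_dend.invert_yaxis()
    ax_row_dend.axis("off")

    if has_groups:
        ax_strip = fig.add_subplot(gs[1, 1])
        groups = [matrix.group_labels.get(run, "") for run in orders.run_order]
        palette = plt.get_cmap("tab10")
        unique = sorted(set(groups))
        colors = {g: palette(i % 10) for i, g in enumerate(unique)}
        for i, g in enumerate(groups):
            ax_strip.add_patch(plt.Rectangle((i, 0), 1, 1, color=colors[g]))
        ax_strip.set_xlim(0, len(groups))
        ax_strip.set_ylim(0, 1)
        ax_strip.axis("off")
        handles = [plt.Rectangle((0, 0), 1, 1, color=colors[g]) for g in unique]
        ax_strip.legend(
            handles, unique, loc="lower left", bbox_to_anchor=(0, 1.5), ncol=len(unique),
            frameon=False, fontsize=8,
        )

    ax_heat = fig.add_subplot(gs[2, 1])
    # gray colormap: 0 -> black (low rank, dark), 100 -> white (high rank)
    im = ax_heat.imshow(
        ordered.to_numpy(), aspect="auto", cmap="gray", vmin=0, vmax=100,
        interpolation="nearest",
    )
    ax_heat.set_xticks(range(n_cols))
    ax_heat.set_xticklabels(orders.run_order, rotation=90, fontsize=8)
    ax_heat.set_yticks(range(n_rows))
    ax_heat.set_yticklabels(orders.metric_order, fontsize=8)
    ax_heat.yaxis.tick_right()
    cbar = fig.colorbar(im, ax=ax_heat, fraction=0.03, pad=0.12)
    cbar.set_label("percentile rank", fontsize=8)

    fig.savefig(img_path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return {"image": img_path, "tsv": tsv_path}
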