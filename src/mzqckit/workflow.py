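"""Assemble computed QC metrics into mzQC documents.

The demonstration workflow computes three metric groups — basic acquisition
metrics, ion injection-time statistics, and identification-derived metrics —
possibly by different tools, writes one partial mzQC document per group, and
merges the partial documents into a single report. These helpers build the
run-quality elements and documents around the metric computations, and
define the default metric panel the clustered heatmap shows.
"""

from __future__ import annotations

import datetime
from typing import Optional, Sequence

from .metrics import PsmRecord, Run, identification_metrics, injection_time_stats, run_basic_metrics
from .model import InputFile, Metadata, MzQcDocument, QualityElement, QualityMetric
from .registry import METRICS
from .report import MetricSelector
from .synthetic import software_ref, toy_cv_reference

__all__ = [
    "run_quality_element",
    "document_from_elements",
    "extract_document",
    "partial_documents",
    "default_metric_selection",
]

STAGES = ("basic", "injection", "identification")


def _now_iso() -> str:
    return datetime.datetime.now().strftime("%Y-%m-%dT%H:%M:%S")


def run_quality_element(run: Run, metrics: Sequence[QualityMetric]) -> QualityElement:
    """Wrap computed metrics for one run in a runQuality element."""
    return QualityElement(
        metadata=Metadata(
            inputFiles=[
                InputFile(name=f"{run.run_name}.mzML", location=run.source_location)
            ],
            analysisSoftware=[software_ref()],
            label=run.run_name,
        ),
        qualityMetrics=list(metrics),
    )


def document_from_elements(elements: Sequence[QualityElement]) -> MzQcDocument:
    doc = MzQcDocument(
        version="1.0.0",
        creationDate=_now_iso(),
        controlledVocabularies=[toy_cv_reference()],
        runQualities=list(elements),
    )
    doc.check()
    return doc


def _stage_metrics(
    stage: str,
    run: Run,
    psms: Optional[Sequence[PsmRecord]],
    q_threshold: float,
) -> list[QualityMetric]:
    if stage == "basic":
        return run_basic_metrics(run)
    if stage == "injection":
        return injection_time_stats(run)
    if stage == "identification":
        if psms is None:
            raise ValueError("identification metrics need a PSM table")
        return identification_metrics(run, psms, q_threshold)
    raise ValueError(f"unknown stage {stage!r}")


def extract_document(
    runs: Sequence[Run],
    psm_tables: Optional[dict[str, Sequence[PsmRecord]]] = None,
    stages: Sequence[str] = STAGES,
    q_threshold: float = 0.01,
) -> MzQcDocument:
    """One document carrying the selected metric stages for every run."""
    elements = []
    for run in runs:
        metrics: list[QualityMetric] = []
        for stage in stages:
            psms = (psm_tables or {}).get(run.run_name)
            metrics.extend(_stage_metrics(stage, run, psms, q_threshold))
        elements.append(run_quality_element(run, metrics))
    return document_from_elements(elements)


def partial_documents(
    runs: Sequence[Run],
    psm_tables: dict[str, Sequence[PsmRecord]],
    q_threshold: float = 0.01,
) -> dict[str, MzQcDocument]:
    """Three partial documents (one per metric stage) covering every run.

    This mirrors a polyglot QC pipeline where each stage is computed by a
    different tool and exported separately before being merged.
    """
    return {
        stage: extract_document(runs, psm_tables, stages=(stage,), q_threshold=q_threshold)
        for stage in STAGES
    }


def default_metric_selection() -> list[MetricSelector]:
    """The default heatmap panel: one number per metric family per run."""
    m = METRICS
    return [
        MetricSelector(m["ms2_count"].accession, label="MS/MS spectra"),
        MetricSelector(m["id_ms2_count"].accession, label="identified MS/MS"),
        MetricSelector(m["peptide_count"].accession, label="identified peptides"),
        MetricSelector(m["protein_count"].accession, label="identified proteins"),
        MetricSelector(
            m["tic"].accession, reduce=("sum", "intensity"), label="summed TIC"
        ),
        MetricSelector(
            m["base_peak"].accession, reduce=("max", "intensity"), label="max base peak"
        ),
        MetricSelector(
            m["ms1_injection"].accession, reduce=("index", 2), label="MS1 injection mean"
        ),
        MetricSelector(
            m["ms2_injection"].accession, reduce=("index", 2), label="MS2 injection mean"
        ),
        MetricSelector(
            m["ppm_summary"].accession, reduce=("index", 0), label="ppm error mean"
        ),
        MetricSelector(
            m["ppm_summary"].accession, reduce=("index", 1), label="ppm error sd"
        ),
        MetricSelector(
            m["missed_cleavages"].accession,
            reduce=("sum", "count"),
            label="PSMs with missed-cleavage info",
        ),
        MetricSelector(
            m["id_rt_range"].accession, reduce=("span", None), label="identified RT span"
        ),
    ]
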