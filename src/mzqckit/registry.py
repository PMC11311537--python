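"""Catalog of the QC metrics this toolkit computes.

Each metric the demonstration workflow produces is anchored to a term of a
local quality-control vocabulary with the ``QCX`` prefix. The real PSI-MS
CV assigns its own accessions to equivalent concepts; swapping the registry
entries for PSI-MS accessions (and supplying the PSI-MS OBO file to the
validator) is the intended migration path and touches nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["MetricDef", "METRICS", "CV_PREFIX", "ROOT_TERM", "SOFTWARE_TERM"]

CV_PREFIX = "QCX"


@dataclass(frozen=True)
class MetricDef:
    accession: str
    name: str
    value_type: str  # one of cv.VALUE_TYPES
    table_columns: Optional[tuple[str, ...]] = None
    description: str = ""


#: Root of the toy CV's is_a hierarchy.
ROOT_TERM = MetricDef("QCX:4000000", "QC metric", "unspecified")

#: Term identifying this software in analysisSoftware sections.
SOFTWARE_TERM = MetricDef("QCX:9000001", "mzqckit", "unspecified")

#: Term for the mzML input file format.
MZML_FORMAT_TERM = MetricDef("QCX:9000002", "mzML format", "unspecified")

METRICS: dict[str, MetricDef] = {
    "chromatogram_count": MetricDef(
        "QCX:4000001", "number of chromatograms", "scalar-number",
        description="Count of chromatograms recorded with the run.",
    ),
    "mz_range": MetricDef(
        "QCX:4000002", "m/z acquisition range", "tuple",
        description="[min, max] m/z over all acquired peaks.",
    ),
    "rt_range": MetricDef(
        "QCX:4000003", "retention time acquisition range", "tuple",
        description="[min, max] retention time (s) over all spectra.",
    ),
    "tic": MetricDef(
        "QCX:4000004", "total ion chromatogram", "table",
        table_columns=("rt_seconds", "intensity"),
        description="Per-spectrum summed peak intensity over retention time.",
    ),
    "base_peak": MetricDef(
        "QCX:4000005", "base peak intensities", "table",
        table_columns=("rt_seconds", "intensity"),
        description="Per-spectrum maximum peak intensity over retention time.",
    ),
    "ms1_injection": MetricDef(
        "QCX:4000006", "MS1 ion injection time statistics", "tuple",
        description="[min, max, mean, median] injection time (ms) of MS1 spectra.",
    ),
    "ms2_injection": MetricDef(
        "QCX:4000007", "MS2 ion injection time statistics", "tuple",
        description="[min, max, mean, median] injection time (ms) of MS2 spectra.",
    ),
    "ms2_count": MetricDef(
        "QCX:4000010", "number of MS/MS spectra", "scalar-number",
    ),
    "id_ms2_count": MetricDef(
        "QCX:4000011", "number of identified MS/MS spectra", "scalar-number",
    ),
    "peptide_count": MetricDef(
        "QCX:4000012", "number of identified peptides", "scalar-number",
    ),
    "protein_count": MetricDef(
        "QCX:4000013", "number of identified proteins", "scalar-number",
    ),
    "ppm_errors": MetricDef(
        "QCX:4000014", "precursor mass error distribution", "table",
        table_columns=("ppm",),
        description="Signed precursor m/z deviation (ppm), one row per accepted PSM.",
    ),
    "ppm_summary": MetricDef(
        "QCX:4000015", "precursor mass error summary", "tuple",
        description="[mean, sd, median] of the signed ppm deviations.",
    ),
    "missed_cleavages": MetricDef(
        "QCX:4000016", "missed cleavage histogram", "table",
        table_columns=("missed_cleavages", "count"),
        description="Frequency of 0..max missed tryptic cleavages over accepted PSMs.",
    ),
    "id_rt_range": MetricDef(
        "QCX:4000017", "identified retention time range", "tuple",
        description="[min, max] retention time (s) of accepted PSMs.",
    ),
}

BY_ACCESSION: dict[str, MetricDef] = {d.accession: d for d in METRICS.values()}
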