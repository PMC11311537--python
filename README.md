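# mzqckit

A Python toolkit for the **mzQC** file format — the HUPO-PSI standard,
JSON-based exchange format for quality-control information about mass
spectrometry experiments.

MS data are prone to run-to-run variability from sample handling,
instrument drift, and processing choices. QC metrics (spectrum counts,
ion-current traces, identification rates, mass-error distributions, ...)
make that variability visible, but only if they can be stored and exchanged
in a common, semantically unambiguous form. mzQC provides that form:
metrics are grouped into `runQuality` (one MS run) or `setQuality` (a set
of runs) elements, each metric is anchored to a controlled-vocabulary (CV)
term by accession, and values may be scalars, tuples, or columnar tables.
The format communicates quality information; it does not judge the data.

`mzqckit` is aimed at proteomics/metabolomics bioinformaticians building QC
pipelines. It provides:

- **Data model & (de)serialization** — typed containers with
  construction-time invariant checks; lossless JSON read/write with a
  tolerant reader (unknown keys preserved) and a strict writer.
- **Syntactic validation** — structural rule checking with stable rule ids
  and slash-delimited paths; never raises, always returns a findings report.
- **Semantic validation** — CV-aware checks against an OBO vocabulary:
  accession resolution, name agreement, declared value-shape conformance
  (including required table columns), obsolete-term and unlisted-prefix use.
- **QC metrics** — chromatogram count, m/z and RT acquisition ranges, total
  ion chromatogram, base peak intensities, ion injection-time statistics
  per MS level, and identification metrics from PSM tables: spectrum /
  peptide / protein counts, the precursor mass-error (ppm) distribution,
  missed-cleavage counting (trypsin rule: cut after K/R, not before P), and
  the identified RT range. PSMs are filtered at a configurable q-value
  threshold (default 0.01); FDR itself is never recomputed.
- **Merge & report** — coalesce partial mzQC files per run, percentile-rank
  each metric across runs (mean-rank convention, 0–100), cluster both axes
  (average linkage, Euclidean distance over pairwise-complete entries), and
  render a grayscale heatmap with dendrograms plus a TSV of the ranked
  matrix. Darker cells mean lower percentile ranks.
- **Synthetic data** — a seeded generator for an 8-run, two-condition DDA
  experiment with exact ground truth, a toy CV, and a labeled catalog of
  valid/invalid documents, so everything is testable offline.
- **CLI** — `mzqc validate | extract | merge | report | fixtures`.

Key formulas: the theoretical precursor m/z of a peptide with monoisotopic
mass *M* at charge *z* is (*M* + *z*·m<sub>p</sub>)/*z* with
m<sub>p</sub> = 1.00727646688 Da; the signed mass error is
ppm = 10⁶·(m/z<sub>obs</sub> − m/z<sub>theo</sub>)/m/z<sub>theo</sub>;
the percentile rank of *x* among *n* values is
100·(#{v < x} + ½·#{v = x})/*n*.

## Worked example

Generate the synthetic corpus and run the pipeline from the shell:

```bash
mzqc fixtures --seed 7 -o demo
mzqc validate demo/documents/valid-minimal.mzqc
# valid                                (exit code 0)
mzqc validate demo/documents/ragged-table.mzqc
# error: [ragged-table] mzQC/runQualities/0/qualityMetrics/1/value: table columns have unequal lengths
# invalid                              (exit code 1)
```

or drive the library directly:

```python
from mzqckit.synthetic import ExperimentSpec, generate_experiment
from mzqckit.workflow import partial_documents, default_metric_selection
from mzqckit.report import (merge_documents, build_metric_matrix,
                            percentile_rank_matrix, cluster_order, render_report)

spec = ExperimentSpec(seed=7)                    # 8 runs, 2 conditions x 4 replicates
runs, psms, truth = generate_experiment(spec)
merged = merge_documents(list(partial_documents(runs, psms).values()))
matrix = build_metric_matrix(merged, default_metric_selection())
print(matrix.values.iloc[:5, :3].round(1))
```

which prints (three of the eight runs shown):

```
                     run_DMSO_rep1  run_DMSO_rep2  run_DMSO_rep3
MS/MS spectra         1.250000e+03   1.250000e+03   1.250000e+03
identified MS/MS      1.000000e+03   1.000000e+03   1.000000e+03
identified peptides   6.670000e+02   6.780000e+02   6.780000e+02
identified proteins   5.000000e+01   5.000000e+01   5.000000e+01
summed TIC            3.191262e+09   3.160058e+09   3.170282e+09
```

Each run acquired 1250 MS/MS spectra of which 1000 were identified at
q ≤ 0.01 (the generator's 80% identification rate); the 1000 accepted PSMs
collapse to ~670–680 distinct peptides from all 50 synthetic proteins, and
the summed total ion current varies a few percent between runs. Ranking,
clustering and rendering then follow:

```python
ranked = percentile_rank_matrix(matrix)
orders = cluster_order(ranked)
render_report(ranked, orders, "qc_report")   # qc_report.png + qc_report.tsv
```

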