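# Methods

This note documents the models, conventions and numerical choices behind
`mzqckit`, in the spirit of a package reference manual: what each component
assumes, which parameters matter, and what the synthetic data do and do not
emulate.

## The mzQC data model

A document holds a format version (pinned to `1.0.0`; other versions are
rejected at construction with a clear error rather than silently
half-supported), an ISO-8601 creation timestamp (stored verbatim — no
timezone normalization — so read/write round-trips are byte-faithful for
this field), at least one controlled-vocabulary reference, and at least one
`runQuality` or `setQuality` element. Set-level elements must reference at
least two input files, run-level at least one. Metric accessions must be
unique within an element, and input-file names unique within a metadata
block.

Accessions match `^[A-Z]+[A-Z0-9]*:[0-9]+$` — PSI-MS-shaped without
hard-coding one prefix, since local vocabularies (including the bundled toy
CV, prefix `QCX`) are first-class citizens.

Metric values are classified structurally: atom → scalar, list of scalars →
tuple, mapping of equal-length lists → table. Null values, empty
containers, nested lists, and ragged tables are rejected: a metric without
a well-formed value carries no QC information. Tables keep their JSON
column-mapping form for lossless serialization and convert to pandas
DataFrames on demand.

## Serialization

The contract is *structural* round-trip equality (field-by-field,
order-insensitive for mappings, order-sensitive for lists), not byte
equality — JSON mappings are unordered. The reader is tolerant: unknown
keys anywhere in the file are retained on the owning object and re-emitted
on write, for forward compatibility with format evolution; whether the
official schema permits such keys is a question for the schema, not this
toolkit — we merely do not destroy them. The writer omits absent optional
fields (never emits `null`) and refuses invariant-violating documents.
Numbers are emitted with Python's shortest round-trippable representation.
Remote file retrieval is deliberately out of scope; callers fetch text
themselves and use `read_mzqc`.

`read_mzqc(..., strict=False)` skips the invariant check, which is how
deliberately non-conforming documents (e.g. duplicate metric accessions)
are materialized for the semantic validator to report on.

## Validation

Syntactic validation works on the raw JSON tree, collects every finding
(no fail-fast), and never raises — malformed JSON is finding `not-json`.
Findings carry a stable rule id, an `error`/`warning` severity, and a
slash-delimited path with zero-based indices (`mzQC/runQualities/0/...`).
A document is valid iff it has no error-severity findings.

Semantic validation takes a parsed CV and checks: accession resolution
(error), document-vs-CV name agreement (warning — the accession is the
identity carrier, so a divergent display name should not block a report),
declared value-shape conformance including required table columns (error;
a boolean where a number is declared is an error, and numeric/text scalar
mismatches are errors only where the CV is explicit), obsolete-term use
(warning), per-element metric uniqueness and per-metadata input-file
uniqueness (errors), and CV-prefix listing (warning). The severity split
between blocking errors and advisory warnings is this package's design
decision. Since the format gives CV references no prefix field, a prefix
is considered "listed" when it occurs case-insensitively in a reference's
name or URI — a convention, documented here precisely because it is one.

## Controlled-vocabulary handling

The CV is supplied as a local OBO file (offline-first; the real PSI-MS CV
can be dropped in). Only `[Term]` stanzas are interpreted; `id`, `name`,
`def`, `is_a`, and `is_obsolete` are captured. Value shapes are declared
via `xref: value-type:{scalar-number|scalar-text|tuple|table}` and table
columns via `xref: table-columns:a,b`; terms without a declaration are
`unspecified` and exempt from shape checking. How the real PSI-MS CV
encodes table-column requirements differs; mapping its encoding onto these
annotations is the intended swap point (see `mzqckit/registry.py`).
`is_descendant` is reflexive breadth-first reachability over `is_a`; the
query terminates even on cyclic input, and `assert_acyclic` reports cycles
explicitly.

## QC metrics

Units are fixed internally: retention time in seconds, m/z in Thomson,
injection time in milliseconds, masses in Dalton. Readers of
minute-denominated inputs (e.g. mzML scan start times) convert on
ingestion.

- The TIC and base-peak traces are per-spectrum tables over *all* spectra
  (MS1 and MS2); the per-spectrum trace subsumes any scalar reduction, and
  reductions (e.g. summed TIC) are applied at matrix-building time.
- Injection-time statistics are `[min, max, mean, median]` per MS level; a
  level with no recorded injection times is omitted, not reported as zero.
- Peptide masses are monoisotopic: sum of residue masses + water
  (18.0105646863 Da) + bracketed offsets; the constants live in one table
  (`MassTables`) for auditability. ppm error is computed at the m/z level
  (observed vs theoretical m/z at the PSM's charge), not at neutral-mass
  level.
- Missed cleavages follow trypsin by default — internal K/R not followed
  by P — with the residue sets configurable for other proteases.
- Identification metrics are computed over PSMs with q ≤ threshold
  (default 0.01, the conventional 1% working point). The q-value is taken
  from the upstream table as-is regardless of the level at which it was
  estimated; FDR is never recomputed here. Peptide distinctness uses
  modification-stripped sequences — the simpler convention, chosen and
  documented because conventions differ. The ppm summary tuple is
  `[mean, sd, median]` with sample sd (ddof = 1).

The optional mzML reader is built on lxml and covers the subset of mzML
that carries these quantities (MS level, scan times with unit conversion,
injection time, precursor m/z/charge, 32/64-bit plain or zlib peak arrays,
chromatogram count); it is not a general mzML object model.

## Merge and report

Run identity for merging is the location of the element's first input file
(exact string), falling back to its name — the join key is otherwise
undefined by the format. Metrics are unioned; the same accession with
unequal values is a conflict (error by default; `keep-first` with a logged
warning on request, keeping merged reports trustworthy unless the caller
explicitly opts out). Software lists are unioned, CV references
deduplicated by (name, uri, version), set-level elements concatenated, and
the merged document gets a fresh timestamp. Merging is idempotent and
order-insensitive for conflict-free inputs.

Percentile ranking uses the mean-rank convention,
`100·(#below + ½·#ties)/n`, applied **per metric across runs** — ranking
across metrics would mix incomparable units. Ranks therefore lie in
(0, 100), an all-ties vector maps to all-50, and the transform is invariant
under strictly monotone rescaling of a metric.

Clustering is agglomerative with average linkage on Euclidean distances
computed over pairwise-complete entries (a pair of rows/columns with no
overlap is an error naming the offender); linkage and distance are fixed
defaults with a config override, and labels are pre-sorted before linkage
so tie-breaking is deterministic. The heatmap maps rank 0 → black and
100 → white (darker = lower), with dendrograms on both axes and an
optional condition color strip.

## Synthetic data

The generator emulates a two-condition DDA proteomics experiment at desk
scale. Defaults are the study conditions: 8 runs = 2 conditions ("DMSO"
control, "SUF" treatment) × 4 replicates; a 7200 s gradient; 125 MS1
scans/run, each followed by 10 MS2 scans (1250 MS2/run); identification
rate 0.8, giving exactly 1000 accepted PSMs per run at q ≤ 0.01, plus a 5%
decoy fraction above the threshold so the filter is exercised; precursor
mass errors N(μ = 2 ppm, σ = 3 ppm); missed-cleavage mix
(0.6, 0.25, 0.1, 0.05) over 0–3; 20% methionine-oxidation rate. The toy
proteome is 50 random 200-residue proteins; candidate peptides are built by
joining 1–4 consecutive full-digest tryptic fragments, so a peptide's
missed-cleavage count equals its junction count *by construction* —
ground-truth bookkeeping that is independent of the metric-side counter.
Observed m/z values are generated by inverting the ppm formula around the
theoretical m/z, and ground-truth sums/statistics are accumulated with
`math.fsum`/sorting, a different numerical route than the metrics module's
numpy reductions.

What the generator does **not** emulate: chromatographic peak shapes,
isotope envelopes, fragment-spectrum content, shared peptides between
proteins, or condition-dependent effects. Passing tests therefore
demonstrate computational correctness of the metrics and plumbing on data
of realistic shape and size — not robustness to the physics and chemistry
of real instrument output.

All randomness flows from one integer seed through numpy `SeedSequence`
spawning, so outputs are bitwise reproducible. Unit tests run a
scaled-down spec (12 MS1 × 5 MS2 per run); the acceptance checks run the
full default spec, which generates and processes in a few seconds.

## Validation fixtures and oracles

The labeled catalog holds 20 valid documents (hand-built minimal variants
plus seeded random documents), 8 syntactic violations and 7 semantic
violations, each invalid case violating exactly one rule. The syntactic
validator's verdicts are cross-checked against an independent generic
JSON-Schema validation using a locally authored stand-in schema
(`tests/data/mzqc_schema.synthetic.json`). JSON Schema cannot express two
of the structural rules — equal table-column lengths and per-element
accession uniqueness — so the oracle harness adds two small independent
tree-walk checks for exactly those; everything else is the schema's
verdict.

## Known limitations

- The toy CV's accessions are placeholders; swapping in real PSI-MS
  accessions is a registry edit plus supplying the PSI-MS OBO.
- The OBO parser implements the subset needed for CV-anchored validation
  (no typedefs, intersections, or non-`is_a` relationships).
- Cross-document consistency beyond merge conflicts (e.g. contradictory
  metadata for one run in two files) is not checked.
- Statistical outlier testing of runs and longitudinal instrument
  monitoring are out of scope; the report supports visual inspection only.
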