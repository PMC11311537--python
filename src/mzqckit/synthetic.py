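"""Seeded synthetic data: runs, PSM tables, a toy CV, and labeled documents.

Everything the toolkit consumes can be generated here with known ground
truth, so the whole test surface works offline. The experiment generator
emulates a two-condition DDA proteomics experiment at desk scale — by
default 8 runs (4 control "DMSO" replicates, 4 treatment "SUF" replicates)
over a 7200 s gradient, tryptic peptides with up to three missed cleavages,
identifications filtered at q <= 0.01, and precursor mass errors drawn from
a normal distribution. It makes no attempt at realistic chromatographic
peak shapes, isotope envelopes, or fragment-spectrum content: spectra are
random peak lists whose bookkeeping (counts, sums, extrema, drawn errors)
is exact.

All randomness flows from a single integer seed via numpy's SeedSequence,
so identical seeds give bitwise-identical output on any platform.
"""

from __future__ import annotations

import base64
import json
import math
import os
import struct
import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from . import registry
from .metrics import (
    PsmRecord,
    Run,
    Spectrum,
    strip_modifications,
    theoretical_mz,
)
from .model import (
    CvReference,
    InputFile,
    Metadata,
    MzQcDocument,
    QualityElement,
    QualityMetric,
    SoftwareRef,
)

__all__ = [
    "ExperimentSpec",
    "RunGroundTruth",
    "generate_experiment",
    "toy_obo",
    "toy_cv_reference",
    "software_ref",
    "random_document",
    "generate_mzqc_fixture",
    "fixture_case_ids",
    "write_fixture_corpus",
    "write_minimal_mzml",
]

OXIDATION = "[+15.994915]"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ExperimentSpec:
    """Parameters of one synthetic experiment.

    Defaults mirror the shape of an 8-run, two-condition bacterial DDA
    study: 2 conditions x 4 replicates, a 120 min (7200 s) gradient, 125
    MS1 scans per run each followed by 10 data-dependent MS2 scans, an 80%
    identification rate (so 1000 accepted PSMs per run), precursor mass
    errors N(mu=2 ppm, sigma=3 ppm), and a missed-cleavage mix dominated by
    fully cleaved peptides.
    """

    n_runs: int = 8
    conditions: tuple[str, ...] = ("DMSO", "SUF")
    ms1_per_run: int = 125
    ms2_per_ms1: int = 10
    gradient_seconds: float = 7200.0
    ms1_peaks: tuple[int, int] = (60, 120)  # uniform integer range
    ms2_peaks: tuple[int, int] = (15, 40)
    log_intensity_ms1: tuple[float, float] = (12.0, 1.0)  # lognormal mu, sigma
    log_intensity_ms2: tuple[float, float] = (8.0, 1.0)
    injection_ms1: tuple[float, float] = (5.0, 1.0)  # normal mean, sd (ms)
    injection_ms2: tuple[float, float] = (50.0, 10.0)
    ppm_mu: float = 2.0
    ppm_sigma: float = 3.0
    missed_cleavage_probs: tuple[float, ...] = (0.6, 0.25, 0.1, 0.05)
    id_rate: float = 0.8
    decoy_rate: float = 0.05  # fraction of MS2 given a PSM above threshold
    q_threshold: float = 0.01
    oxidation_prob: float = 0.2
    n_proteins: int = 50
    protein_length: int = 200
    chromatogram_count: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 1 or self.ms1_per_run < 1 or self.ms2_per_ms1 < 1:
            raise ValueError("counts must be positive")
        if not math.isclose(sum(self.missed_cleavage_probs), 1.0, abs_tol=1e-9):
            raise ValueError("missed-cleavage probabilities must sum to 1")
        if not 0.0 <= self.id_rate <= 1.0:
            raise ValueError("id_rate must be a fraction")
        if self.n_runs % len(self.conditions):
            raise ValueError("runs must divide evenly over conditions")

    def run_names(self) -> list[str]:
        per = self.n_runs // len(self.conditions)
        return [
            f"run_{cond}_rep{i + 1}"
            for cond in self.conditions
            for i in range(per)
        ]

    def condition_of(self, run_name: str) -> str:
        return run_name.split("_")[1]


@dataclass
class RunGroundTruth:
    """Bookkeeping recorded while generating one run.

    Every field is recomputable by the metrics module from the emitted
    ``Run`` / ``PsmRecord`` objects; integer quantities match exactly and
    floating quantities to rounding error. Sums/means here are accumulated
    with :func:`math.fsum` over plain Python lists — a different route than
    the numpy reductions the metrics module uses.
    """

    n_ms2: int = 0
    n_identified_spectra: int = 0
    n_peptides: int = 0
    n_proteins: int = 0
    tic: list[float] = field(default_factory=list)
    base_peak: list[float] = field(default_factory=list)
    mz_range: tuple[float, float] = (math.inf, -math.inf)
    rt_range: tuple[float, float] = (math.inf, -math.inf)
    injection_stats: dict[int, list[float]] = field(default_factory=dict)
    ppm_sample: list[float] = field(default_factory=list)
    missed_cleavage_hist: dict[int, int] = field(default_factory=dict)
    id_rt_range: Optional[tuple[float, float]] = None
    chromatogram_count: int = 0


def _digest(sequence: str) -> list[str]:
    """Full tryptic digest: cut after K/R except before P."""
    fragments = []
    start = 0
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            fragments.append(sequence[start : i + 1])
            start = i + 1
    fragments.append(sequence[start:])
    return [f for f in fragments if f]


@dataclass(frozen=True)
class _Candidate:
    peptide: str
    protein: str
    missed_cleavages: int  # junctions joined, exact by construction


def _build_peptide_pools(
    rng: np.random.Generator, spec: ExperimentSpec
) -> dict[int, list[_Candidate]]:
    """Toy proteome and its tryptic peptide candidates, binned by missed cleavages."""
    max_mc = len(spec.missed_cleavage_probs) - 1
    pools: dict[int, list[_Candidate]] = {mc: [] for mc in range(max_mc + 1)}
    for p in range(spec.n_proteins):
        protein = f"SYNP{p + 1:05d}"
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=spec.protein_length))
        fragments = _digest(seq)
        for i in range(len(fragments)):
            for mc in range(max_mc + 1):
                if i + mc >= len(fragments):
                    break
                peptide = "".join(fragments[i : i + mc + 1])
                if 7 <= len(peptide) <= 30:
                    pools[mc].append(_Candidate(peptide, protein, mc))
    for mc, pool in pools.items():
        if not pool:
            raise ValueError(f"proteome yields no peptides with {mc} missed cleavages")
    return pools


def _sorted_stats(values: list[float]) -> list[float]:
    ordered = sorted(values)
    n = len(ordered)
    mean = math.fsum(ordered) / n
    median = (
        ordered[n // 2]
        if n % 2
        else (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0
    )
    return [ordered[0], ordered[-1], mean, median]


def generate_experiment(
    spec: ExperimentSpec,
) -> tuple[list[Run], dict[str, list[PsmRecord]], dict[str, RunGroundTruth]]:
    """Generate runs, per-run PSM lists, and ground truth for ``spec``.

    Deterministic given ``spec.seed``. Accepted PSMs (q <= threshold) per
    run number exactly ``round(id_rate * n_ms2)``; a further ``decoy_rate``
    fraction of MS2 spectra receives a PSM above the threshold so that the
    q-value filter is actually exercised.
    """
    spec.validate()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_runs + 1)
    pools = _build_peptide_pools(np.random.default_rng(children[0]), spec)
    max_mc = len(spec.missed_cleavage_probs) - 1

    runs: list[Run] = []
    psm_tables: dict[str, list[PsmRecord]] = {}
    truths: dict[str, RunGroundTruth] = {}

    for r, run_name in enumerate(spec.run_names()):
        rng = np.random.default_rng(children[r + 1])
        truth = RunGroundTruth(chromatogram_count=spec.chromatogram_count)
        spectra: list[Spectrum] = []
        ms2_indices: list[int] = []
        scan = 0
        dt = spec.gradient_seconds / spec.ms1_per_run
        mz_lo, mz_hi = math.inf, -math.inf
        for i in range(spec.ms1_per_run):
            rt1 = (i + 0.25) * dt
            scan += 1
            n_peaks = int(rng.integers(*spec.ms1_peaks))
            mz = np.sort(rng.uniform(300.0, 1500.0, size=n_peaks))
            inten = rng.lognormal(*spec.log_intensity_ms1, size=n_peaks)
            inj = max(0.1, float(rng.normal(*spec.injection_ms1)))
            spectra.append(
                Spectrum(
                    native_id=f"scan={scan}",
                    ms_level=1,
                    rt_seconds=rt1,
                    mz_array=mz,
                    intensity_array=inten,
                    injection_time_ms=inj,
                )
            )
            truth.injection_stats.setdefault(1, []).append(inj)
            truth.tic.append(math.fsum(inten.tolist()))
            truth.base_peak.append(max(inten.tolist()))
            mz_lo = min(mz_lo, float(mz[0]))
            mz_hi = max(mz_hi, float(mz[-1]))
            for j in range(spec.ms2_per_ms1):
                scan += 1
                rt2 = rt1 + (j + 1) * dt / (spec.ms2_per_ms1 + 2)
                n_peaks = int(rng.integers(*spec.ms2_peaks))
                mz2 = np.sort(rng.uniform(100.0, 1300.0, size=n_peaks))
                inten2 = rng.lognormal(*spec.log_intensity_ms2, size=n_peaks)
                inj2 = max(0.1, float(rng.normal(*spec.injection_ms2)))
                ms2_indices.append(len(spectra))
                spectra.append(
                    Spectrum(
                        native_id=f"scan={scan}",
                        ms_level=2,
                        rt_seconds=rt2,
                        mz_array=mz2,
                        intensity_array=inten2,
                        precursor_mz=float(rng.uniform(400.0, 1000.0)),
                        precursor_charge=2,
                        injection_time_ms=inj2,
                    )
                )
                truth.injection_stats.setdefault(2, []).append(inj2)
                truth.tic.append(math.fsum(inten2.tolist()))
                truth.base_peak.append(max(inten2.tolist()))
                mz_lo = min(mz_lo, float(mz2[0]))
                mz_hi = max(mz_hi, float(mz2[-1]))

        n_ms2 = len(ms2_indices)
        truth.n_ms2 = n_ms2
        truth.mz_range = (mz_lo, mz_hi)
        truth.rt_range = (spectra[0].rt_seconds, spectra[-1].rt_seconds)

        n_accept = int(round(spec.id_rate * n_ms2))
        # a search yielding no accepted identifications emits an empty table
        n_decoy = int(round(spec.decoy_rate * n_ms2)) if n_accept else 0
        chosen = rng.choice(ms2_indices, size=n_accept + n_decoy, replace=False)
        accepted_idx, decoy_idx = chosen[:n_accept], chosen[n_accept:]

        psms: list[PsmRecord] = []
        peptide_set: set[str] = set()
        protein_set: set[str] = set()
        id_rts: list[float] = []
        for k, idx in enumerate(accepted_idx):
            spectrum = spectra[idx]
            mc = int(rng.choice(max_mc + 1, p=spec.missed_cleavage_probs))
            cand = pools[mc][int(rng.integers(len(pools[mc])))]
            peptide = cand.peptide
            if "M" in peptide and rng.random() < spec.oxidation_prob:
                m_pos = peptide.index("M")
                peptide = peptide[: m_pos + 1] + OXIDATION + peptide[m_pos + 1 :]
            charge = int(rng.choice([2, 3]))
            ppm = float(rng.normal(spec.ppm_mu, spec.ppm_sigma))
            theo = theoretical_mz(peptide, charge)
            observed = theo * (1.0 + ppm * 1e-6)
            q = float(rng.uniform(0.0, spec.q_threshold * 0.99))
            spectrum.precursor_mz = observed
            spectrum.precursor_charge = charge
            psms.append(
                PsmRecord(
                    spectrum_native_id=spectrum.native_id,
                    rt_seconds=spectrum.rt_seconds,
                    observed_mz=observed,
                    charge=charge,
                    peptide=peptide,
                    proteins=[cand.protein],
                    q_value=q,
                )
            )
            truth.ppm_sample.append(ppm)
            truth.missed_cleavage_hist[mc] = truth.missed_cleavage_hist.get(mc, 0) + 1
            peptide_set.add(strip_modifications(peptide))
            protein_set.add(cand.protein)
            id_rts.append(spectrum.rt_seconds)
        for idx in decoy_idx:
            spectrum = spectra[idx]
            cand = pools[0][int(rng.integers(len(pools[0])))]
            psms.append(
                PsmRecord(
                    spectrum_native_id=spectrum.native_id,
                    rt_seconds=spectrum.rt_seconds,
                    observed_mz=float(rng.uniform(400.0, 1000.0)),
                    charge=2,
                    peptide=cand.peptide,
                    proteins=[cand.protein],
                    q_value=float(rng.uniform(spec.q_threshold * 2, 1.0)),
                )
            )
        truth.n_identified_spectra = len(accepted_idx)
        truth.n_peptides = len(peptide_set)
        truth.n_proteins = len(protein_set)
        if id_rts:
            truth.id_rt_range = (min(id_rts), max(id_rts))

        run = Run(
            run_name=run_name,
            source_location=f"file:///data/{run_name}.mzML",
            spectra=spectra,
            chromatogram_count=spec.chromatogram_count,
        )
        runs.append(run)
        psm_tables[run_name] = psms
        truths[run_name] = truth
    return runs, psm_tables, truths


def injection_truth_stats(truth: RunGroundTruth, level: int) -> Optional[list[float]]:
    """[min, max, mean, median] of the recorded injection times, by sorting."""
    times = truth.injection_stats.get(level)
    return _sorted_stats(times) if times else None


# --- toy controlled vocabulary ---------------------------------------------

OBSOLETE_TERM_ACCESSION = "QCX:9000009"
EXTERNAL_TERM_ACCESSION = "OTHER:0000001"


def toy_obo() -> str:
    """OBO text of the toy QC vocabulary backing the metric registry.

    Besides one term per registry metric (each ``is_a`` the root QC-metric
    term, with ``xref: value-type:`` and ``xref: table-columns:``
    annotations), the vocabulary defines the toolkit's software term, an
    mzML file-format term, one obsolete term, and one term under a foreign
    prefix, so every semantic-validation rule has something to bite on.
    """
    lines = [
        "format-version: 1.2",
        "data-version: 0.1.0",
        "ontology: qcx",
        "",
        "[Term]",
        f"id: {registry.ROOT_TERM.accession}",
        f"name: {registry.ROOT_TERM.name}",
        'def: "Root of the toy QC metric hierarchy."',
        "",
    ]
    for d in registry.METRICS.values():
        lines += [
            "[Term]",
            f"id: {d.accession}",
            f"name: {d.name}",
        ]
        if d.description:
            lines.append(f'def: "{d.description}"')
        lines.append(f"is_a: {registry.ROOT_TERM.accession} ! {registry.ROOT_TERM.name}")
        lines.append(f"xref: value-type:{d.value_type}")
        if d.table_columns:
            lines.append("xref: table-columns:" + ",".join(d.table_columns))
        lines.append("")
    lines += [
        "[Term]",
        f"id: {registry.SOFTWARE_TERM.accession}",
        f"name: {registry.SOFTWARE_TERM.name}",
        'def: "This toolkit, as an analysis-software term."',
        "",
        "[Term]",
        f"id: {registry.MZML_FORMAT_TERM.accession}",
        f"name: {registry.MZML_FORMAT_TERM.name}",
        'def: "mzML mass-spectrometry data file format."',
        "",
        "[Term]",
        f"id: {OBSOLETE_TERM_ACCESSION}",
        "name: legacy metric count",
        'def: "Superseded demonstration metric."',
        "is_obsolete: true",
        "xref: value-type:scalar-number",
        "",
        "[Term]",
        f"id: {EXTERNAL_TERM_ACCESSION}",
        "name: external software tool",
        'def: "A term under a prefix the toy documents do not list."',
        "",
    ]
    return "\n".join(lines)


def toy_cv_reference() -> CvReference:
    return CvReference(
        name="Toy mass-spectrometry quality-control vocabulary (QCX)",
        uri="file:///cv/qcx.obo",
        version="0.1.0",
    )


def software_ref() -> SoftwareRef:
    return SoftwareRef(
        accession=registry.SOFTWARE_TERM.accession,
        name=registry.SOFTWARE_TERM.name,
        version="0.1.0",
    )


def run_metadata(run_name: str, location: Optional[str] = None, label: Optional[str] = None) -> Metadata:
    return Metadata(
        inputFiles=[
            InputFile(
                name=f"{run_name}.mzML",
                location=location or f"file:///data/{run_name}.mzML",
            )
        ],
        analysisSoftware=[software_ref()],
        label=label or run_name,
    )


# --- random valid documents -------------------------------------------------

_TIMESTAMP = "2024-02-20T12:00:00"


def _random_metric(rng: np.random.Generator, d: registry.MetricDef) -> QualityMetric:
    if d.value_type == "scalar-number":
        value = (
            int(rng.integers(0, 100000))
            if rng.random() < 0.5
            else float(np.round(rng.uniform(0, 1e6), 6))
        )
    elif d.value_type == "scalar-text":
        value = f"text-{int(rng.integers(0, 1000))}"
    elif d.value_type == "tuple":
        value = [float(np.round(v, 6)) for v in rng.uniform(0, 1000, size=int(rng.integers(2, 6)))]
    else:  # table
        n = int(rng.integers(2, 8))
        cols = d.table_columns or ("a", "b")
        value = {c: [float(np.round(v, 6)) for v in rng.uniform(0, 1000, size=n)] for c in cols}
    return QualityMetric(accession=d.accession, name=d.name, value=value)


def random_document(seed_or_rng: Union[int, np.random.Generator]) -> MzQcDocument:
    """A random valid mzQC document drawing metrics from the registry.

    Documents vary in element counts, metric subsets, optional fields, and
    occasionally carry unknown extra keys (exercising the tolerant-reader /
    faithful-writer contract). Every produced document passes syntactic and
    semantic validation against the toy CV.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    defs = list(registry.METRICS.values())
    n_runs = int(rng.integers(1, 4))
    run_qualities = []
    for i in range(n_runs):
        picks = rng.choice(len(defs), size=int(rng.integers(1, len(defs) + 1)), replace=False)
        metrics = [_random_metric(rng, defs[int(p)]) for p in sorted(picks)]
        elem = QualityElement(
            metadata=run_metadata(f"rand_run_{i}"),
            qualityMetrics=metrics,
        )
        if rng.random() < 0.3:
            elem.extras["x-note"] = f"extra-{int(rng.integers(100))}"
        run_qualities.append(elem)
    set_qualities = []
    if rng.random() < 0.4:
        picks = rng.choice(len(defs), size=2, replace=False)
        set_qualities.append(
            QualityElement(
                metadata=Metadata(
                    inputFiles=[
                        InputFile(name="a.mzML", location="file:///data/a.mzML"),
                        InputFile(name="b.mzML", location="file:///data/b.mzML"),
                    ],
                    analysisSoftware=[software_ref()],
                ),
                qualityMetrics=[_random_metric(rng, defs[int(p)]) for p in sorted(picks)],
                kind="setQuality",
            )
        )
    doc = MzQcDocument(
        version="1.0.0",
        creationDate=_TIMESTAMP,
        controlledVocabularies=[toy_cv_reference()],
        runQualities=run_qualities,
        setQualities=set_qualities,
        description="synthetic document" if rng.random() < 0.5 else None,
        contactName="QC Robot" if rng.random() < 0.3 else None,
    )
    if rng.random() < 0.3:
        doc.extras["x-generator"] = "synthetic"
    doc.check()
    return doc


# --- labeled validation fixtures --------------------------------------------


@dataclass(frozen=True)
class FixtureCase:
    case_id: str
    kind: str  # "valid" | "syntactic" | "semantic"
    expected_rule: Optional[str] = None
    expected_path: Optional[str] = None


def _minimal_body() -> dict:
    d = registry.METRICS["ms2_count"]
    return {
        "version": "1.0.0",
        "creationDate": _TIMESTAMP,
        "controlledVocabularies": [
            {
                "name": toy_cv_reference().name,
                "uri": toy_cv_reference().uri,
                "version": "0.1.0",
            }
        ],
        "runQualities": [
            {
                "metadata": {
                    "inputFiles": [
                        {"name": "run1.mzML", "location": "file:///data/run1.mzML"}
                    ],
                    "analysisSoftware": [
                        {
                            "accession": registry.SOFTWARE_TERM.accession,
                            "name": registry.SOFTWARE_TERM.name,
                            "version": "0.1.0",
                        }
                    ],
                },
                "qualityMetrics": [
                    {"accession": d.accession, "name": d.name, "value": 12345}
                ],
            }
        ],
    }


def _wrap(body: dict) -> str:
    return json.dumps({"mzQC": body}, indent=1)


def _table_metric(ragged: bool = False) -> dict:
    d = registry.METRICS["tic"]
    value = {"rt_seconds": [1.0, 2.0], "intensity": [10.0] if ragged else [10.0, 20.0]}
    return {"accession": d.accession, "name": d.name, "value": value}


def _case_builders() -> dict[str, Callable[[], tuple[str, FixtureCase]]]:
    cases: dict[str, Callable[[], tuple[str, FixtureCase]]] = {}

    def add(case_id: str, kind: str, rule: Optional[str], path: Optional[str], make: Callable[[], str]) -> None:
        cases[case_id] = lambda: (make(), FixtureCase(case_id, kind, rule, path))

    # valid variants
    add("valid-minimal", "valid", None, None, lambda: _wrap(_minimal_body()))

    def valid_table() -> str:
        body = _minimal_body()
        body["runQualities"][0]["qualityMetrics"].append(_table_metric())
        return _wrap(body)

    add("valid-table-metric", "valid", None, None, valid_table)

    def valid_set() -> str:
        body = _minimal_body()
        d = registry.METRICS["peptide_count"]
        body["setQualities"] = [
            {
                "metadata": {
                    "inputFiles": [
                        {"name": "a.mzML", "location": "file:///a.mzML"},
                        {"name": "b.mzML", "location": "file:///b.mzML"},
                    ],
                    "analysisSoftware": body["runQualities"][0]["metadata"][
                        "analysisSoftware"
                    ],
                },
                "qualityMetrics": [
                    {"accession": d.accession, "name": d.name, "value": 777}
                ],
            }
        ]
        return _wrap(body)

    add("valid-set-quality", "valid", None, None, valid_set)

    def valid_extras() -> str:
        body = _minimal_body()
        body["x-vendor-extension"] = {"note": "kept verbatim"}
        return _wrap(body)

    add("valid-extra-keys", "valid", None, None, valid_extras)

    def valid_random(k: int) -> str:
        from .io import write_mzqc

        return write_mzqc(random_document(1000 + k))

    for k in range(16):
        add(f"valid-random-{k:02d}", "valid", None, None, lambda k=k: valid_random(k))

    # syntactic violations — exactly one rule each
    add("not-json", "syntactic", "not-json", "mzQC", lambda: '{"mzQC": broken')
    add(
        "missing-root",
        "syntactic",
        "missing-root",
        "mzQC",
        lambda: json.dumps({"notMzQC": {}}),
    )

    def missing_version() -> str:
        body = _minimal_body()
        del body["version"]
        return _wrap(body)

    add("missing-version", "syntactic", "required-missing", "mzQC/version", missing_version)

    def bad_version() -> str:
        body = _minimal_body()
        body["version"] = "1.0"
        return _wrap(body)

    add("bad-version", "syntactic", "bad-version", "mzQC/version", bad_version)

    def no_elements() -> str:
        body = _minimal_body()
        del body["runQualities"]
        return _wrap(body)

    add("no-quality-elements", "syntactic", "no-quality-elements", "mzQC", no_elements)

    def ragged() -> str:
        body = _minimal_body()
        body["runQualities"][0]["qualityMetrics"].append(_table_metric(ragged=True))
        return _wrap(body)

    add(
        "ragged-table",
        "syntactic",
        "ragged-table",
        "mzQC/runQualities/0/qualityMetrics/1/value",
        ragged,
    )

    def duplicate_metric() -> str:
        body = _minimal_body()
        metric = dict(body["runQualities"][0]["qualityMetrics"][0])
        body["runQualities"][0]["qualityMetrics"].append(metric)
        return _wrap(body)

    add(
        "duplicate-metric",
        "syntactic",
        "duplicate-metric",
        "mzQC/runQualities/0/qualityMetrics/1",
        duplicate_metric,
    )

    def bad_accession() -> str:
        body = _minimal_body()
        body["runQualities"][0]["qualityMetrics"][0]["accession"] = "qcx:12"
        return _wrap(body)

    add(
        "bad-accession",
        "syntactic",
        "bad-accession",
        "mzQC/runQualities/0/qualityMetrics/0/accession",
        bad_accession,
    )

    # semantic violations — exactly one rule each (against the toy CV)
    def sem_unknown() -> str:
        body = _minimal_body()
        body["runQualities"][0]["qualityMetrics"][0]["accession"] = "QCX:4999999"
        return _wrap(body)

    add(
        "sem-unknown-accession",
        "semantic",
        "unknown-accession",
        "mzQC/runQualities/0/qualityMetrics/0",
        sem_unknown,
    )

    def sem_name() -> str:
        body = _minimal_body()
        body["runQualities"][0]["qualityMetrics"][0]["name"] = "number of spectra"
        return _wrap(body)

    add(
        "sem-name-mismatch",
        "semantic",
        "name-mismatch",
        "mzQC/runQualities/0/qualityMetrics/0",
        sem_name,
    )

    def sem_type() -> str:
        body = _minimal_body()
        d = registry.METRICS["tic"]
        body["runQualities"][0]["qualityMetrics"][0] = {
            "accession": d.accession,
            "name": d.name,
            "value": 42,
        }
        return _wrap(body)

    add(
        "sem-value-type-mismatch",
        "semantic",
        "value-type-mismatch",
        "mzQC/runQualities/0/qualityMetrics/0",
        sem_type,
    )

    def sem_obsolete() -> str:
        body = _minimal_body()
        body["runQualities"][0]["qualityMetrics"][0] = {
            "accession": OBSOLETE_TERM_ACCESSION,
            "name": "legacy metric count",
            "value": 3,
        }
        return _wrap(body)

    add(
        "sem-obsolete-term",
        "semantic",
        "obsolete-term",
        "mzQC/runQualities/0/qualityMetrics/0",
        sem_obsolete,
    )

    def sem_duplicate() -> str:
        body = _minimal_body()
        metric = dict(body["runQualities"][0]["qualityMetrics"][0])
        body["runQualities"][0]["qualityMetrics"].append(metric)
        return _wrap(body)

    add(
        "sem-duplicate-metric",
        "semantic",
        "duplicate-metric",
        "mzQC/runQualities/0/qualityMetrics/1",
        sem_duplicate,
    )

    def sem_dup_file() -> str:
        body = _minimal_body()
        files = body["runQualities"][0]["metadata"]["inputFiles"]
        files.append(dict(files[0]))
        return _wrap(body)

    add(
        "sem-duplicate-input-file",
        "semantic",
        "duplicate-input-file",
        "mzQC/runQualities/0/metadata/inputFiles/1",
        sem_dup_file,
    )

    def sem_prefix() -> str:
        body = _minimal_body()
        body["runQualities"][0]["qualityMetrics"][0] = {
            "accession": EXTERNAL_TERM_ACCESSION,
            "name": "external software tool",
            "value": 1,
        }
        return _wrap(body)

    add(
        "sem-unlisted-cv-prefix",
        "semantic",
        "unlisted-cv-prefix",
        "mzQC/runQualities/0/qualityMetrics/0",
        sem_prefix,
    )

    return cases


_CASES = _case_builders()


def fixture_case_ids(kind: Optional[str] = None) -> list[str]:
    """Ids of the documented fixture catalog, optionally filtered by kind."""
    if kind is None:
        return list(_CASES)
    return [cid for cid in _CASES if _CASES[cid]()[1].kind == kind]


def generate_mzqc_fixture(case_id: str) -> tuple[str, FixtureCase]:
    """Return ``(text, expected)`` for one case of the fixture catalog."""
    try:
        builder = _CASES[case_id]
    except KeyError:
        raise KeyError(f"unknown fixture case {case_id!r}") from None
    return builder()


# --- fixture corpus on disk -------------------------------------------------


def write_fixture_corpus(out_dir: Union[str, os.PathLike], seed: int = 0) -> dict:
    """Write the full offline corpus: CV, runs, PSM tables, document catalog.

    Returns a manifest of the written paths. Runs use a scaled-down
    experiment (so the corpus stays small); the catalog documents and the
    toy CV are seed-independent.
    """
    from .io import write_mzqc  # local import to avoid a cycle at module load
    from .metrics import run_to_json, write_psm_tsv

    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"cv": None, "runs": {}, "psms": {}, "documents": {}, "mzml": {}}

    cv_path = os.path.join(out, "qcx.obo")
    with open(cv_path, "w", encoding="utf-8") as fh:
        fh.write(toy_obo())
    manifest["cv"] = cv_path

    spec = ExperimentSpec(seed=seed, ms1_per_run=12, ms2_per_ms1=5)
    runs, psm_tables, _ = generate_experiment(spec)
    for run in runs:
        run_path = os.path.join(out, f"{run.run_name}.run.json")
        with open(run_path, "w", encoding="utf-8") as fh:
            fh.write(run_to_json(run))
        manifest["runs"][run.run_name] = run_path
        psm_path = os.path.join(out, f"{run.run_name}.psms.tsv")
        write_psm_tsv(psm_tables[run.run_name], psm_path)
        manifest["psms"][run.run_name] = psm_path
    mzml_path = os.path.join(out, f"{runs[0].run_name}.synthetic.mzML")
    write_minimal_mzml(runs[0], mzml_path)
    manifest["mzml"][runs[0].run_name] = mzml_path

    doc_dir = os.path.join(out, "documents")
    os.makedirs(doc_dir, exist_ok=True)
    for case_id in fixture_case_ids():
        text, case = generate_mzqc_fixture(case_id)
        path = os.path.join(doc_dir, f"{case_id}.mzqc")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        manifest["documents"][case_id] = {
            "path": path,
            "kind": case.kind,
            "expected_rule": case.expected_rule,
        }
    with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# --- minimal mzML writing (for exercising the optional reader) --------------


def _b64(array: np.ndarray) -> str:
    packed = struct.pack(f"<{array.size}d", *array.astype(float))
    return base64.b64encode(zlib.compress(packed)).decode("ascii")


def write_minimal_mzml(run: Run, path: Union[str, os.PathLike]) -> None:
    """Write a small, schema-shaped mzML file for the given run.

    Synthetic stand-in for instrument output: just enough mzML (spectrum
    metadata, zlib-compressed 64-bit peak arrays, an empty chromatogram
    list of the declared length) for an mzML parser to read it back.
    """
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        "  <cvList count=\"1\">",
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        "  </cvList>",
        '  <run id="%s">' % run.run_name,
        '    <spectrumList count="%d">' % len(run.spectra),
    ]
    for i, s in enumerate(run.spectra):
        mz_b64 = _b64(s.mz_array)
        int_b64 = _b64(s.intensity_array)
        parts.append(
            f'      <spectrum index="{i}" id="{s.native_id}" defaultArrayLength="{s.mz_array.size}">'
        )
        parts.append(
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>'
        )
        parts.append("        <scanList count=\"1\">")
        parts.append("          <scan>")
        parts.append(
            '            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{s.rt_seconds / 60.0!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
        )
        if s.injection_time_ms is not None:
            parts.append(
                '            <cvParam cvRef="MS" accession="MS:1000927" name="ion injection time" '
                f'value="{s.injection_time_ms!r}" unitCvRef="UO" unitAccession="UO:0000028" unitName="millisecond"/>'
            )
        parts.append("          </scan>")
        parts.append("        </scanList>")
        if s.ms_level == 2 and s.precursor_mz is not None:
            parts.append("        <precursorList count=\"1\">")
            parts.append("          <precursor>")
            parts.append("            <selectedIonList count=\"1\">")
            parts.append("              <selectedIon>")
            parts.append(
                '                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
                f'value="{s.precursor_mz!r}"/>'
            )
            if s.precursor_charge is not None:
                parts.append(
                    '                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" '
                    f'value="{s.precursor_charge}"/>'
                )
            parts.append("              </selectedIon>")
            parts.append("            </selectedIonList>")
            parts.append("          </precursor>")
            parts.append("        </precursorList>")
        parts.append("        <binaryDataArrayList count=\"2\">")
        for name, acc, payload in (
            ("m/z array", "MS:1000514", mz_b64),
            ("intensity array", "MS:1000515", int_b64),
        ):
            parts.append(f'          <binaryDataArray encodedLength="{len(payload)}">')
            parts.append(
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            )
            parts.append(
                '            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>'
            )
            parts.append(
                f'            <cvParam cvRef="MS" accession="{acc}" name="{name}"/>'
            )
            parts.append(f"            <binary>{payload}</binary>")
            parts.append("          </binaryDataArray>")
        parts.append("        </binaryDataArrayList>")
        parts.append("      </spectrum>")
    parts.append("    </spectrumList>")
    parts.append('    <chromatogramList count="%d">' % run.chromatogram_count)
    for c in range(run.chromatogram_count):
        arr = _b64(np.asarray([0.0, 1.0]))
        parts.append(
            f'      <chromatogram index="{c}" id="chrom={c}" defaultArrayLength="2">'
        )
        parts.append("        <binaryDataArrayList count=\"1\">")
        parts.append(f'          <binaryDataArray encodedLength="{len(arr)}">')
        parts.append(
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
        )
        parts.append(
            '            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>'
        )
        parts.append(
            '            <cvParam cvRef="MS" accession="MS:1000595" name="time array"/>'
        )
        parts.append(f"            <binary>{arr}</binary>")
        parts.append("          </binaryDataArray>")
        parts.append("        </binaryDataArrayList>")
        parts.append("      </chromatogram>")
    parts.append("    </chromatogramList>")
    parts.append("  </run>")
    parts.append("</mzML>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts))
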