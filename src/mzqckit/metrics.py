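"""QC metric computation from MS runs and peptide-spectrum-match tables.

This module implements the demonstration workflow's metric panel: basic
acquisition metrics (chromatogram count, m/z and retention-time ranges,
total ion chromatogram, base peak intensities), ion injection-time
statistics per MS level, and identification-derived metrics (spectrum /
peptide / protein counts, the precursor mass-error distribution in ppm,
missed-cleavage counting under the trypsin rule, and the retention-time
range of successful identifications). Each computation is packaged as
CV-anchored :class:`~mzqckit.model.QualityMetric` objects ready for an mzQC
report.

Units: retention time is seconds everywhere, m/z in Thomson, injection time
in milliseconds, masses in Dalton. Readers of minute-denominated inputs
must convert on ingestion.
"""

from __future__ import annotations

import csv
import json
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .model import MetricValue, QualityMetric
from .registry import METRICS, MetricDef

__all__ = [
    "Spectrum",
    "Run",
    "PsmRecord",
    "MassTables",
    "MONOISOTOPIC",
    "MetricError",
    "run_basic_metrics",
    "injection_time_stats",
    "peptide_monoisotopic_mass",
    "theoretical_mz",
    "ppm_error",
    "count_missed_cleavages",
    "strip_modifications",
    "identification_metrics",
    "read_psm_tsv",
    "write_psm_tsv",
    "run_to_json",
    "run_from_json",
]


class MetricError(ValueError):
    pass


@dataclass
class Spectrum:
    """One mass spectrum: peak arrays plus acquisition metadata."""

    native_id: str
    ms_level: int
    rt_seconds: float
    mz_array: np.ndarray
    intensity_array: np.ndarray
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    injection_time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz_array = np.asarray(self.mz_array, dtype=float)
        self.intensity_array = np.asarray(self.intensity_array, dtype=float)
        if self.mz_array.shape != self.intensity_array.shape:
            raise MetricError("mz and intensity arrays differ in length")
        if self.rt_seconds < 0:
            raise MetricError("negative retention time")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise MetricError("MS2 spectrum without precursor m/z")


@dataclass
class Run:
    """An in-memory MS run: time-ordered spectra plus run-level counts."""

    run_name: str
    source_location: str
    spectra: list[Spectrum]
    chromatogram_count: int = 0

    def __post_init__(self) -> None:
        rts = [s.rt_seconds for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            # stable sort keeps equal-RT spectra in input order
            self.spectra = sorted(self.spectra, key=lambda s: s.rt_seconds)
        if self.chromatogram_count < 0:
            raise MetricError("negative chromatogram count")

    def ms2_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass
class PsmRecord:
    """One peptide-spectrum match from an upstream search engine.

    ``peptide`` is a residue sequence with optional bracketed mass offsets,
    e.g. ``"PEPTM[+15.994915]IDE"``. ``q_value`` is the confidence estimate
    assigned upstream; this toolkit filters on it but never recomputes FDR.
    """

    spectrum_native_id: str
    rt_seconds: float
    observed_mz: float
    charge: int
    peptide: str
    proteins: list[str]
    q_value: float

    def __post_init__(self) -> None:
        if not self.peptide:
            raise MetricError("empty peptide sequence")
        if self.charge < 1:
            raise MetricError("charge must be >= 1")
        if not 0.0 <= self.q_value <= 1.0:
            raise MetricError("q-value outside [0, 1]")


@dataclass(frozen=True)
class MassTables:
    """Monoisotopic mass constants, kept in one place for auditability."""

    residue_mono: dict = field(
        default_factory=lambda: dict(
            G=57.02146372,
            A=71.03711379,
            S=87.03202841,
            P=97.05276385,
            V=99.06841391,
            T=101.04767847,
            C=103.00918496,
            L=113.08406398,
            I=113.08406398,
            N=114.04292744,
            D=115.02694302,
            Q=128.05857751,
            K=128.09496302,
            E=129.04259309,
            M=131.04048491,
            H=137.05891186,
            F=147.06841391,
            R=156.10111102,
            Y=163.06332853,
            W=186.07931295,
        )
    )
    water_mono: float = 18.0105646863
    proton_mono: float = 1.00727646688


MONOISOTOPIC = MassTables()

_MOD_RE = re.compile(r"\[[+-]?\d+(?:\.\d+)?\]")
_TOKEN_RE = re.compile(r"([A-Za-z])|\[([+-]?\d+(?:\.\d+)?)\]")


def _metric(definition: MetricDef, raw) -> QualityMetric:
    return QualityMetric(
        accession=definition.accession,
        name=definition.name,
        value=MetricValue.from_raw(raw),
        description=definition.description or None,
    )


def run_basic_metrics(run: Run) -> list[QualityMetric]:
    """Basic acquisition metrics of one run.

    Emits the chromatogram count (scalar), the acquired m/z range (tuple
    ``[min, max]`` over all peaks of all spectra), the acquired retention
    time range (tuple over spectra), the total ion chromatogram (table with
    one row per spectrum: retention time, summed intensity) and the base
    peak intensity trace (table: retention time, maximum intensity).
    """
    if not run.spectra:
        raise MetricError("empty run")
    rts = [float(s.rt_seconds) for s in run.spectra]
    tic = [float(s.intensity_array.sum()) if s.intensity_array.size else 0.0 for s in run.spectra]
    base = [float(s.intensity_array.max()) if s.intensity_array.size else 0.0 for s in run.spectra]
    populated = [s for s in run.spectra if s.mz_array.size]
    if not populated:
        raise MetricError("run has no peaks")
    mz_min = min(float(s.mz_array.min()) for s in populated)
    mz_max = max(float(s.mz_array.max()) for s in populated)
    return [
        _metric(METRICS["chromatogram_count"], run.chromatogram_count),
        _metric(METRICS["mz_range"], [mz_min, mz_max]),
        _metric(METRICS["rt_range"], [min(rts), max(rts)]),
        _metric(METRICS["tic"], {"rt_seconds": rts, "intensity": tic}),
        _metric(METRICS["base_peak"], {"rt_seconds": rts, "intensity": base}),
    ]


def injection_time_stats(run: Run) -> list[QualityMetric]:
    """Ion injection-time statistics per MS level.

    For MS1 and MS2 separately, the tuple ``[min, max, mean, median]`` of
    injection times (ms) over the spectra that record one. A level with no
    recorded injection times is omitted rather than reported as zero.
    """
    if not run.spectra:
        raise MetricError("empty run")
    out: list[QualityMetric] = []
    for level, key in ((1, "ms1_injection"), (2, "ms2_injection")):
        times = [
            float(s.injection_time_ms)
            for s in run.spectra
            if s.ms_level == level and s.injection_time_ms is not None
        ]
        if not times:
            continue
        stats = [
            min(times),
            max(times),
            float(np.mean(times)),
            float(np.median(times)),
        ]
        out.append(_metric(METRICS[key], stats))
    return out


def strip_modifications(peptide: str) -> str:
    """Remove bracketed mass offsets, leaving the bare residue sequence."""
    return _MOD_RE.sub("", peptide)


def peptide_monoisotopic_mass(peptide: str, tables: MassTables = MONOISOTOPIC) -> float:
    """Monoisotopic mass (Da) of a peptide with optional bracketed offsets.

    The mass is the sum of residue monoisotopic masses plus one water plus
    any bracketed offsets, e.g. ``"M[+15.994915]K"``. Unknown residue
    letters are reported with their position.
    """
    if not peptide:
        raise MetricError("empty peptide")
    mass = tables.water_mono
    pos = 0
    consumed = 0
    for match in _TOKEN_RE.finditer(peptide):
        if match.start() != consumed:
            raise MetricError(f"unparseable peptide at position {consumed}")
        consumed = match.end()
        residue, offset = match.groups()
        if residue is not None:
            pos += 1
            try:
                mass += tables.residue_mono[residue.upper()]
            except KeyError:
                raise MetricError(
                    f"unknown residue {residue!r} at position {pos}"
                ) from None
        else:
            mass += float(offset)
    if consumed != len(peptide):
        raise MetricError(f"unparseable peptide at position {consumed}")
    return mass


def theoretical_mz(
    peptide: str, charge: int, tables: MassTables = MONOISOTOPIC
) -> float:
    """Theoretical precursor m/z: ``(M + z * proton) / z``."""
    if charge < 1:
        raise MetricError("charge must be >= 1")
    return (peptide_monoisotopic_mass(peptide, tables) + charge * tables.proton_mono) / charge


def ppm_error(observed_mz: float, theoretical: float) -> float:
    """Signed relative m/z deviation in parts per million."""
    if theoretical <= 0:
        raise MetricError("theoretical m/z must be positive")
    return 1e6 * (observed_mz - theoretical) / theoretical


def count_missed_cleavages(peptide: str, *, cut_after: str = "KR", no_cut_before: str = "P") -> int:
    """Number of internal protease sites left uncut in ``peptide``.

    Default rule is trypsin: a site is an internal K or R not followed by P.
    Bracketed modification offsets are ignored. The rule is configurable
    through ``cut_after`` / ``no_cut_before`` for other proteases.
    """
    seq = strip_modifications(peptide)
    if not seq:
        raise MetricError("empty peptide")
    return sum(
        1
        for i in range(len(seq) - 1)
        if seq[i] in cut_after and seq[i + 1] not in no_cut_before
    )


def identification_metrics(
    run: Run,
    psms: Sequence[PsmRecord],
    q_threshold: float = 0.01,
    tables: MassTables = MONOISOTOPIC,
) -> list[QualityMetric]:
    """Identification-derived metrics over PSMs accepted at ``q_threshold``.

    Emits: number of MS/MS spectra in the run; number of identified MS/MS
    spectra (distinct spectrum ids among accepted PSMs); number of
    identified peptides (distinct modification-stripped sequences); number
    of identified proteins (distinct accessions); the precursor mass-error
    distribution (ppm per accepted PSM, plus a ``[mean, sd, median]``
    summary, sd with one delta degree of freedom); the missed-cleavage
    histogram; and the retention-time range of accepted PSMs. With zero
    accepted PSMs the count metrics are 0 and distribution metrics omitted.
    """
    if not 0.0 < q_threshold <= 1.0:
        raise MetricError("q-value threshold must be in (0, 1]")
    known_ids = {s.native_id for s in run.spectra}
    unknown = sorted({p.spectrum_native_id for p in psms} - known_ids)
    if unknown:
        raise MetricError(f"PSMs reference unknown spectrum ids: {unknown}")

    accepted = [p for p in psms if p.q_value <= q_threshold]
    n_ms2 = len(run.ms2_spectra())
    out = [
        _metric(METRICS["ms2_count"], n_ms2),
        _metric(METRICS["id_ms2_count"], len({p.spectrum_native_id for p in accepted})),
        _metric(
            METRICS["peptide_count"],
            len({strip_modifications(p.peptide) for p in accepted}),
        ),
        _metric(
            METRICS["protein_count"],
            len({acc for p in accepted for acc in p.proteins}),
        ),
    ]
    if not accepted:
        return out

    ppms = [
        ppm_error(p.observed_mz, theoretical_mz(p.peptide, p.charge, tables))
        for p in accepted
    ]
    summary = [
        float(np.mean(ppms)),
        float(np.std(ppms, ddof=1)) if len(ppms) > 1 else 0.0,
        float(np.median(ppms)),
    ]
    mcs = [count_missed_cleavages(p.peptide) for p in accepted]
    bins = list(range(max(mcs) + 1))
    counts = [mcs.count(b) for b in bins]
    rts = [p.rt_seconds for p in accepted]
    out.extend(
        [
            _metric(METRICS["ppm_errors"], {"ppm": ppms}),
            _metric(METRICS["ppm_summary"], summary),
            _metric(METRICS["missed_cleavages"], {"missed_cleavages": bins, "count": counts}),
            _metric(METRICS["id_rt_range"], [min(rts), max(rts)]),
        ]
    )
    return out


# --- PSM table and run exchange formats -------------------------------------

PSM_COLUMNS = (
    "spectrum_id",
    "rt_seconds",
    "observed_mz",
    "charge",
    "peptide",
    "proteins",
    "q_value",
)


def read_psm_tsv(path: Union[str, os.PathLike]) -> list[PsmRecord]:
    """Read a tab-delimited PSM table.

    Expected header: ``spectrum_id, rt_seconds, observed_mz, charge,
    peptide, proteins, q_value``; ``proteins`` is semicolon-delimited.
    """
    records: list[PsmRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(PSM_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise MetricError(f"PSM table lacks column(s): {sorted(missing)}")
        for row in reader:
            records.append(
                PsmRecord(
                    spectrum_native_id=row["spectrum_id"],
                    rt_seconds=float(row["rt_seconds"]),
                    observed_mz=float(row["observed_mz"]),
                    charge=int(row["charge"]),
                    peptide=row["peptide"],
                    proteins=[p for p in row["proteins"].split(";") if p],
                    q_value=float(row["q_value"]),
                )
            )
    return records


def write_psm_tsv(psms: Iterable[PsmRecord], path: Union[str, os.PathLike]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for p in psms:
            writer.writerow(
                [
                    p.spectrum_native_id,
                    repr(p.rt_seconds),
                    repr(p.observed_mz),
                    p.charge,
                    p.peptide,
                    ";".join(p.proteins),
                    repr(p.q_value),
                ]
            )


def run_to_json(run: Run) -> str:
    """Serialize a run to the toolkit's JSON exchange form (lossless)."""
    payload = {
        "runName": run.run_name,
        "sourceLocation": run.source_location,
        "chromatogramCount": run.chromatogram_count,
        "spectra": [
            {
                "nativeId": s.native_id,
                "msLevel": s.ms_level,
                "rtSeconds": s.rt_seconds,
                "mz": s.mz_array.tolist(),
                "intensity": s.intensity_array.tolist(),
                "precursorMz": s.precursor_mz,
                "precursorCharge": s.precursor_charge,
                "injectionTimeMs": s.injection_time_ms,
            }
            for s in run.spectra
        ],
    }
    return json.dumps(payload)


def run_from_json(text: str) -> Run:
    payload = json.loads(text)
    return Run(
        run_name=payload["runName"],
        source_location=payload["sourceLocation"],
        chromatogram_count=payload["chromatogramCount"],
        spectra=[
            Spectrum(
                native_id=s["nativeId"],
                ms_level=s["msLevel"],
                rt_seconds=s["rtSeconds"],
                mz_array=np.asarray(s["mz"], dtype=float),
                intensity_array=np.asarray(s["intensity"], dtype=float),
                precursor_mz=s.get("precursorMz"),
                precursor_charge=s.get("precursorCharge"),
                injection_time_ms=s.get("injectionTimeMs"),
            )
            for s in payload["spectra"]
        ],
    )
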