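"""QC metric computations against independent oracles."""

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzqckit.metrics import (
    MONOISOTOPIC,
    MetricError,
    PsmRecord,
    Run,
    Spectrum,
    count_missed_cleavages,
    identification_metrics,
    injection_time_stats,
    peptide_monoisotopic_mass,
    ppm_error,
    read_psm_tsv,
    run_basic_metrics,
    run_from_json,
    run_to_json,
    strip_modifications,
    theoretical_mz,
    write_psm_tsv,
)
from mzqckit.registry import METRICS


def _by_accession(metrics):
    return {m.accession: m for m in metrics}


def _spectrum(native_id="scan=1", level=1, rt=10.0, mz=(500.0,), inten=(7.0,), **kw):
    return Spectrum(
        native_id=native_id,
        ms_level=level,
        rt_seconds=rt,
        mz_array=np.asarray(mz, dtype=float),
        intensity_array=np.asarray(inten, dtype=float),
        **kw,
    )


class TestMasses:
    def test_glycine(self):
        assert peptide_monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-5)

    def test_additivity(self):
        diff = peptide_monoisotopic_mass("GG") - peptide_monoisotopic_mass("G")
        assert diff == pytest.approx(MONOISOTOPIC.residue_mono["G"], abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(MetricError, match="empty"):
            peptide_monoisotopic_mass("")

    def test_unknown_residue_names_position(self):
        with pytest.raises(MetricError, match="position 3"):
            peptide_monoisotopic_mass("GGXG")

    def test_bracketed_offset_added(self):
        base = peptide_monoisotopic_mass("MK")
        assert peptide_monoisotopic_mass("M[+15.994915]K") == pytest.approx(
            base + 15.994915, abs=1e-9
        )

    def test_strip_modifications(self):
        assert strip_modifications("M[+15.994915]KR[-1.5]P") == "MKRP"


class TestTheoreticalMz:
    def test_singly_charged(self):
        m = peptide_monoisotopic_mass("PEPTIDE")
        assert theoretical_mz("PEPTIDE", 1) == pytest.approx(m + 1.00728, abs=1e-5)

    def test_charge_two_formula(self):
        m = peptide_monoisotopic_mass("PEPTIDE")
        expected = (m + 2 * MONOISOTOPIC.proton_mono) / 2
        assert theoretical_mz("PEPTIDE", 2) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_charge(self):
        assert theoretical_mz("PEPTIDEK", 1) > theoretical_mz("PEPTIDEK", 2)

    def test_zero_charge_rejected(self):
        with pytest.raises(MetricError):
            theoretical_mz("PEPTIDE", 0)


class TestPpmError:
    @pytest.mark.parametrize(
        "observed,theoretical,expected",
        [(1000.010, 1000.000, 10.0), (1000.0, 1000.0, 0.0), (999.990, 1000.0, -10.0)],
    )
    def test_arithmetic(self, observed, theoretical, expected):
        assert ppm_error(observed, theoretical) == pytest.approx(expected, abs=1e-9)

    def test_direct_formula_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            theo = rng.uniform(200, 2000)
            obs = theo + rng.normal(0, 0.01)
            assert ppm_error(obs, theo) == 1e6 * (obs - theo) / theo

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(MetricError):
            ppm_error(500.0, 0.0)


def _mc_oracle(seq: str) -> int:
    """Regex enumeration of internal K/R sites not followed by P."""
    return len(re.findall(r"[KR](?=[^P])", seq))


class TestMissedCleavages:
    @pytest.mark.parametrize(
        "peptide,expected",
        [
            ("PEPTIDE", 0),
            ("ALKGR", 1),
            ("AKPGR", 0),
            ("KKKK", 3),
            ("KPKPKP", 0),
            ("RKR", 2),
            ("M[+15.994915]KAR", 1),
        ],
    )
    def test_examples(self, peptide, expected):
        assert count_missed_cleavages(peptide) == expected

    @settings(derandomize=True, max_examples=300)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_matches_regex_oracle(self, seq):
        assert count_missed_cleavages(seq) == _mc_oracle(seq)


class TestInjectionTimes:
    def test_three_values(self):
        run = Run(
            run_name="r",
            source_location="f",
            spectra=[
                _spectrum(f"s{i}", level=2, rt=float(i), precursor_mz=500.0, injection_time_ms=t)
                for i, t in enumerate([10.0, 20.0, 30.0])
            ],
        )
        [metric] = injection_time_stats(run)
        assert metric.accession == METRICS["ms2_injection"].accession
        assert metric.value.data == [10.0, 30.0, 20.0, 20.0]

    def test_constant_values(self):
        run = Run(
            run_name="r",
            source_location="f",
            spectra=[
                _spectrum(f"s{i}", rt=float(i), injection_time_ms=4.5) for i in range(5)
            ],
        )
        [metric] = injection_time_stats(run)
        assert metric.value.data == [4.5, 4.5, 4.5, 4.5]

    def test_level_without_data_omitted(self):
        run = Run(
            run_name="r",
            source_location="f",
            spectra=[_spectrum("s1", injection_time_ms=None)],
        )
        assert injection_time_stats(run) == []

    def test_against_sorting_oracle(self):
        rng = np.random.default_rng(99)
        times = rng.uniform(1, 100, size=500)
        run = Run(
            run_name="r",
            source_location="f",
            spectra=[
                _spectrum(f"s{i}", rt=float(i), injection_time_ms=float(t))
                for i, t in enumerate(times)
            ],
        )
        [metric] = injection_time_stats(run)
        ordered = sorted(times)
        expected = [
            ordered[0],
            ordered[-1],
            math.fsum(ordered) / len(ordered),
            (ordered[249] + ordered[250]) / 2,
        ]
        for got, want in zip(metric.value.data, expected):
            assert got == pytest.approx(want, rel=1e-9)


class TestBasicMetrics:
    def test_single_one_peak_spectrum(self):
        run = Run(run_name="r", source_location="f", spectra=[_spectrum()], chromatogram_count=0)
        by = _by_accession(run_basic_metrics(run))
        assert by[METRICS["chromatogram_count"].accession].value.data == 0
        assert by[METRICS["mz_range"].accession].value.data == [500.0, 500.0]
        assert by[METRICS["tic"].accession].value.data["intensity"] == [7.0]
        assert by[METRICS["base_peak"].accession].value.data["intensity"] == [7.0]
        assert by[METRICS["rt_range"].accession].value.data == [10.0, 10.0]

    def test_tic_exact_for_integer_intensities(self):
        rng = np.random.default_rng(3)
        spectra = []
        expected = []
        for i in range(50):
            inten = rng.integers(1, 1000, size=rng.integers(1, 40)).astype(float)
            mz = np.sort(rng.uniform(100, 1500, size=inten.size))
            spectra.append(_spectrum(f"s{i}", rt=float(i), mz=mz, inten=inten))
            expected.append(sum(int(v) for v in inten))
        run = Run(run_name="r", source_location="f", spectra=spectra)
        by = _by_accession(run_basic_metrics(run))
        assert by[METRICS["tic"].accession].value.data["intensity"] == expected

    def test_empty_run_rejected(self):
        with pytest.raises(MetricError, match="empty run"):
            run_basic_metrics(Run(run_name="r", source_location="f", spectra=[]))


class TestIdentificationMetrics:
    def _run_and_psm(self, observed=None, charge=2, q=0.001):
        spectrum = _spectrum("s1", level=2, rt=42.0, precursor_mz=500.0)
        peptide = "PEPTIDEK"
        theo = theoretical_mz(peptide, charge)
        psm = PsmRecord(
            spectrum_native_id="s1",
            rt_seconds=42.0,
            observed_mz=theo if observed is None else observed,
            charge=charge,
            peptide=peptide,
            proteins=["P1"],
            q_value=q,
        )
        return Run(run_name="r", source_location="f", spectra=[spectrum]), psm

    def test_perfect_match_gives_zero_ppm(self):
        run, psm = self._run_and_psm()
        by = _by_accession(identification_metrics(run, [psm]))
        assert by[METRICS["ppm_errors"].accession].value.data["ppm"] == [0.0]
        assert by[METRICS["id_rt_range"].accession].value.data == [42.0, 42.0]

    def test_all_rejected_gives_zero_counts(self):
        run, psm = self._run_and_psm(q=1.0)
        by = _by_accession(identification_metrics(run, [psm], q_threshold=0.01))
        assert by[METRICS["id_ms2_count"].accession].value.data == 0
        assert by[METRICS["peptide_count"].accession].value.data == 0
        assert by[METRICS["protein_count"].accession].value.data == 0
        assert METRICS["ppm_errors"].accession not in by

    def test_unknown_native_id_rejected(self):
        run, psm = self._run_and_psm()
        psm.spectrum_native_id = "scan=404"
        with pytest.raises(MetricError, match="scan=404"):
            identification_metrics(run, [psm])

    def test_counts_match_ground_truth(self, small_experiment):
        spec, runs, psm_tables, truth = small_experiment
        for run in runs:
            t = truth[run.run_name]
            by = _by_accession(
                identification_metrics(run, psm_tables[run.run_name], spec.q_threshold)
            )
            assert by[METRICS["ms2_count"].accession].value.data == t.n_ms2
            assert by[METRICS["id_ms2_count"].accession].value.data == t.n_identified_spectra
            assert by[METRICS["peptide_count"].accession].value.data == t.n_peptides
            assert by[METRICS["protein_count"].accession].value.data == t.n_proteins
            hist = by[METRICS["missed_cleavages"].accession].value.data
            got = dict(zip(hist["missed_cleavages"], hist["count"]))
            assert {k: v for k, v in got.items() if v} == t.missed_cleavage_hist
            assert sum(hist["count"]) == t.n_identified_spectra

    def test_invariant_count_ordering(self, small_experiment):
        spec, runs, psm_tables, _ = small_experiment
        for run in runs:
            by = _by_accession(
                identification_metrics(run, psm_tables[run.run_name], spec.q_threshold)
            )
            n_ms2 = by[METRICS["ms2_count"].accession].value.data
            n_id = by[METRICS["id_ms2_count"].accession].value.data
            n_pep = by[METRICS["peptide_count"].accession].value.data
            accepted = [
                p for p in psm_tables[run.run_name] if p.q_value <= spec.q_threshold
            ]
            assert 0 <= n_id <= n_ms2
            assert 0 <= n_pep <= len(accepted)


def test_psm_tsv_roundtrip(tmp_path, small_experiment):
    _, runs, psm_tables, _ = small_experiment
    psms = psm_tables[runs[0].run_name]
    path = tmp_path / "psms.tsv"
    write_psm_tsv(psms, path)
    assert read_psm_tsv(path) == psms


def test_run_json_roundtrip(small_experiment):
    _, runs, _, _ = small_experiment
    run = runs[0]
    again = run_from_json(run_to_json(run))
    assert again.run_name == run.run_name
    assert len(again.spectra) == len(run.spectra)
    s0, s1 = run.spectra[5], again.spectra[5]
    assert np.array_equal(s0.mz_array, s1.mz_array)
    assert s0.injection_time_ms == s1.injection_time_ms
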