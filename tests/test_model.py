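"""Construction-time invariants of the mzQC data model."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzqckit.model import (
    CvReference,
    InputFile,
    Metadata,
    ModelError,
    QualityElement,
    QualityMetric,
    SoftwareRef,
    add_metric,
    classify_value,
    new_document,
)


def _metadata(n_files=1):
    return Metadata(
        inputFiles=[
            InputFile(name=f"run{i}.mzML", location=f"file:///data/run{i}.mzML")
            for i in range(n_files)
        ],
        analysisSoftware=[SoftwareRef(accession="QCX:9000001", name="mzqckit", version="0.1.0")],
    )


def _element(accessions=("QCX:4000010",), kind="runQuality", n_files=1):
    return QualityElement(
        metadata=_metadata(n_files),
        qualityMetrics=[
            QualityMetric(accession=a, name=f"metric {a}", value=1) for a in accessions
        ],
        kind=kind,
    )


def _doc(**kw):
    defaults = dict(
        version="1.0.0",
        creationDate="2024-02-20T12:00:00",
        cvRefs=[CvReference(name="QCX vocabulary", uri="file:///cv.obo")],
        runQualities=[_element()],
    )
    defaults.update(kw)
    return new_document(**defaults)


class TestClassifyValue:
    @pytest.mark.parametrize(
        "raw,kind",
        [
            (42, "scalar"),
            (3.25, "scalar"),
            ("ok", "scalar"),
            (True, "scalar"),
            ([1, 2, 3], "tuple"),
            (["a", 1, 2.5], "tuple"),
            ({"RT": [1, 2], "TIC": [10, 20]}, "table"),
        ],
    )
    def test_kinds(self, raw, kind):
        assert classify_value(raw) == kind

    @pytest.mark.parametrize(
        "raw,fragment",
        [
            (None, "null"),
            ([], "empty tuple"),
            ({}, "empty table"),
            ({"RT": [1, 2], "TIC": [10]}, "ragged"),
            ([[1, 2]], "scalars"),
            ({"RT": 5}, "not a list"),
        ],
    )
    def test_rejections(self, raw, fragment):
        with pytest.raises(ModelError, match=fragment):
            classify_value(raw)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.recursive(
            st.one_of(
                st.integers(),
                st.floats(allow_nan=False, allow_infinity=False),
                st.text(max_size=5),
                st.booleans(),
            ),
            lambda leaf: st.lists(leaf, min_size=1, max_size=4),
            max_leaves=8,
        )
    )
    def test_classification_stable_for_scalars_and_flat_lists(self, raw):
        """classify is total and stable over atoms and flat scalar lists."""
        try:
            kind = classify_value(raw)
        except ModelError:
            # nested lists are legitimately rejected
            assert isinstance(raw, list)
            return
        assert kind == classify_value(raw)


class TestDocumentInvariants:
    def test_minimal_valid_document(self):
        doc = _doc()
        doc.check()  # idempotent re-validation
        assert len(doc.runQualities) == 1

    def test_no_quality_elements(self):
        with pytest.raises(ModelError, match="no quality elements"):
            _doc(runQualities=[])

    def test_malformed_version(self):
        with pytest.raises(ModelError, match="malformed version"):
            _doc(version="1.0")

    def test_unsupported_version_rejected(self):
        with pytest.raises(ModelError, match="unsupported version"):
            _doc(version="2.0.0")

    def test_malformed_timestamp(self):
        with pytest.raises(ModelError, match="malformed timestamp"):
            _doc(creationDate="20 Feb 2024")

    def test_empty_cv_list(self):
        with pytest.raises(ModelError, match="no controlled vocabularies"):
            _doc(cvRefs=[])

    def test_set_level_needs_two_files(self):
        with pytest.raises(ModelError, match="at least 2 input files"):
            _doc(
                runQualities=[],
                setQualities=[_element(kind="setQuality", n_files=1)],
            )
        _doc(runQualities=[], setQualities=[_element(kind="setQuality", n_files=2)])

    def test_duplicate_input_file_names(self):
        elem = _element()
        elem.metadata.inputFiles.append(elem.metadata.inputFiles[0])
        with pytest.raises(ModelError, match="duplicate input file"):
            _doc(runQualities=[elem])

    def test_duplicate_metric_accessions(self):
        with pytest.raises(ModelError, match="duplicate metric accession"):
            _doc(runQualities=[_element(("QCX:1", "QCX:1"))])

    def test_bad_accession_pattern(self):
        with pytest.raises(ModelError, match="malformed accession"):
            _doc(runQualities=[_element(("qcx:0001",))])


class TestAddMetric:
    def test_add_and_count(self):
        elem = _element(())
        assert len(elem.qualityMetrics) == 0
        add_metric(elem, QualityMetric(accession="QCX:4000010", name="x", value=7))
        assert len(elem.qualityMetrics) == 1

    def test_duplicate_refused(self):
        elem = _element(("QCX:4000010",))
        with pytest.raises(ModelError, match="duplicate metric"):
            add_metric(elem, QualityMetric(accession="QCX:4000010", name="x", value=7))
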