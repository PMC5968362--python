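"""First-stage filtering, agreement statistics, frequencies, mapping tallies."""

import numpy as np
import pytest

from phenolex.curate import (
    AgreementSummary,
    ConceptAnnotation,
    ConceptRecord,
    MappingStatus,
    RejectionReason,
    agreement_table,
    anonymity_filter,
    cohen_kappa,
    concept_frequencies,
    first_stage_filter,
    mapping_summary,
    read_annotations_csv,
    write_concept_records_csv,
)
from phenolex.preprocess import Corpus, Document


# --------------------------------------------------------------------------
# First-stage filter
# --------------------------------------------------------------------------

def test_first_stage_filter_reason_codes():
    kept, removed = first_stage_filter(
        ["y", "of_the", "thought_disorder", "123", "p_walked"],
        stopwords={"of", "the"},
    )
    assert kept == ["thought_disorder"]
    assert removed["y"] == RejectionReason.TOKENISATION_FAILURE
    assert removed["p_walked"] == RejectionReason.TOKENISATION_FAILURE
    assert removed["of_the"] == RejectionReason.STOPWORD_ONLY
    assert removed["123"] == RejectionReason.NON_WORD


def test_first_stage_filter_empty_input_rejected():
    with pytest.raises(ValueError):
        first_stage_filter([], stopwords=set())


def test_first_stage_filter_default_stopwords():
    kept, removed = first_stage_filter(["of_the", "guarded"])
    assert kept == ["guarded"]
    assert removed["of_the"] == RejectionReason.STOPWORD_ONLY


# --------------------------------------------------------------------------
# Cohen's kappa and agreement tables
# --------------------------------------------------------------------------

def test_kappa_perfect_agreement():
    a = {"t1": "Speech", "t2": "Thought", "t3": "Speech"}
    assert cohen_kappa(a, dict(a)) == pytest.approx(1.0)


def test_kappa_hand_2x2():
    """p_o = 0.5 and p_e = 0.5 from the marginals gives kappa = 0."""
    a = {"t1": "A", "t2": "A", "t3": "B", "t4": "B"}
    b = {"t1": "A", "t2": "B", "t3": "B", "t4": "A"}
    assert cohen_kappa(a, b) == pytest.approx(0.0)


def test_kappa_constant_identical_annotators():
    a = {"t1": "Other", "t2": "Other"}
    assert cohen_kappa(a, dict(a)) == 1.0


def test_kappa_disjoint_term_sets_rejected():
    with pytest.raises(ValueError):
        cohen_kappa({"t1": "Speech"}, {"t2": "Speech"})


def test_kappa_matches_confusion_matrix_oracle():
    rng = np.random.default_rng(31)
    cats = ["Speech", "Thought", "Other"]
    for _ in range(25):
        n = int(rng.integers(4, 40))
        terms = [f"t{i}" for i in range(n)]
        a = {t: cats[rng.integers(3)] for t in terms}
        b = {t: cats[rng.integers(3)] for t in terms}
        p_o = sum(a[t] == b[t] for t in terms) / n
        p_e = sum(
            (sum(a[t] == c for t in terms) / n) * (sum(b[t] == c for t in terms) / n)
            for c in cats
        )
        if p_e == 1.0:
            continue
        brute = (p_o - p_e) / (1 - p_e)
        assert cohen_kappa(a, b) == pytest.approx(brute)


def test_agreement_table_hand_count():
    a = {"t1": "Speech", "t2": "Speech", "t3": "Other"}
    summary = agreement_table(a, dict(a))
    assert summary.counts == {"Speech": 2, "Other": 1}
    assert summary.total == 3
    assert summary.substantive == 2


def test_agreement_table_no_agreements():
    a = {"t1": "Speech", "t2": "Thought"}
    b = {"t1": "Thought", "t2": "Speech"}
    summary = agreement_table(a, b)
    assert summary.total == 0 and summary.counts == {}


def test_agreement_total_equals_equal_category_count():
    rng = np.random.default_rng(37)
    cats = ["Speech", "Thought", "Perception", "Other"]
    terms = [f"t{i}" for i in range(50)]
    a = {t: cats[rng.integers(4)] for t in terms}
    b = {t: cats[rng.integers(4)] for t in terms}
    summary = agreement_table(a, b)
    assert summary.total == sum(a[t] == b[t] for t in terms)


def test_annotation_category_closed_set():
    ConceptAnnotation("t", "Speech", "ann1")
    with pytest.raises(ValueError):
        ConceptAnnotation("t", "Banter", "ann1")


# --------------------------------------------------------------------------
# Frequencies and anonymity
# --------------------------------------------------------------------------

def _corpus():
    return Corpus(
        [
            Document("p1", "d1", "Patient shows apathy today."),
            Document("p1", "d2", "Apathy persists; poor eye contact."),
            Document("p2", "d3", "Good eye contact, no concerns."),
        ]
    )


def test_concept_frequencies_hand_counts():
    records = {r.term: r for r in concept_frequencies(_corpus(), ["apath", "eye_contact", "stupor"])}
    assert (records["apath"].patient_count, records["apath"].document_count) == (1, 2)
    assert (records["eye_contact"].patient_count, records["eye_contact"].document_count) == (2, 2)
    assert (records["stupor"].patient_count, records["stupor"].document_count) == (0, 0)


def test_document_count_at_least_patient_count(small_corpus):
    _, corpus, truth = small_corpus
    stems = [p for _, p in truth.pc_lexicon][:5]
    for r in concept_frequencies(corpus, stems):
        assert r.document_count >= r.patient_count


def test_concept_record_rejects_impossible_counts():
    with pytest.raises(ValueError):
        ConceptRecord("x", patient_count=5, document_count=3)


def test_anonymity_filter_boundary():
    records = [
        ConceptRecord("low", patient_count=10, document_count=40),
        ConceptRecord("high", patient_count=11, document_count=44),
    ]
    kept = anonymity_filter(records, min_patients=10)
    assert [r.term for r in kept] == ["high"]
    assert anonymity_filter([], min_patients=10) == []


def test_anonymity_filter_idempotent_and_monotone():
    rng = np.random.default_rng(41)
    records = [
        ConceptRecord(f"t{i}", patient_count=int(c), document_count=int(c) * 2)
        for i, c in enumerate(rng.integers(0, 30, size=40))
    ]
    once = anonymity_filter(records, 10)
    assert anonymity_filter(once, 10) == once
    stricter = anonymity_filter(records, 15)
    assert {r.term for r in stricter} <= {r.term for r in once}


# --------------------------------------------------------------------------
# Mapping summaries
# --------------------------------------------------------------------------

def _record(term, status):
    return ConceptRecord(term, 20, 40, mapping_status=status)


def test_mapping_summary_hand_count():
    records = [
        _record("a", MappingStatus.DIRECT),
        _record("b", MappingStatus.NOVEL),
        _record("c", MappingStatus.NOVEL),
    ]
    summary = mapping_summary(records)
    assert (summary.direct, summary.synonym_partial, summary.novel) == (1, 0, 2)
    assert summary.total == len(records)


def test_mapping_summary_empty_and_invalid():
    empty = mapping_summary([])
    assert (empty.direct, empty.synonym_partial, empty.novel) == (0, 0, 0)
    with pytest.raises(ValueError):
        mapping_summary([_record("a", None)])


def test_agreement_summary_is_label_agnostic():
    summary = AgreementSummary({"Speech": 3, "Mood/Anxiety/Affect": 2, "Other": 4})
    assert summary.total == 9
    assert summary.substantive == 5


# --------------------------------------------------------------------------
# File round-trips
# --------------------------------------------------------------------------

def test_annotation_csv_roundtrip(tmp_path):
    path = tmp_path / "ann.csv"
    path.write_text("term,category,annotator\nguarded,Speech,a1\nguarded,Other,a2\n")
    anns = read_annotations_csv(path)
    assert anns[0] == ConceptAnnotation("guarded", "Speech", "a1")


def test_concept_records_csv_written(tmp_path):
    records = [
        ConceptRecord(
            "guarded",
            patient_count=12,
            document_count=30,
            categories={"a1": "Speech", "a2": "Speech"},
            mapping_status=MappingStatus.DIRECT,
            snomed_id="12345",
        )
    ]
    path = tmp_path / "records.csv"
    write_concept_records_csv(records, path)
    text = path.read_text()
    assert "guarded,12,30,Speech,Speech,12345,direct" in text
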