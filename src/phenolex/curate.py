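"""Post-selection curation analytics.

Selected clusters still hold tokenisation debris and stop-word
compounds; the first-stage filter clears those mechanically before any
human sees the list.  The remaining concepts carry two independent
expert category annotations (eight substantive psychiatric-assessment
categories plus a residual Other), inter-annotator agreement is
summarised with Cohen's kappa, corpus frequencies are counted per
unique patient and unique document, an anonymity rule discards concepts
seen in too few patients, and terminology-mapping outcomes (direct /
synonym-or-partial / novel) are tallied.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from sklearn.metrics import cohen_kappa_score

from .preprocess import Corpus

__all__ = [
    "CATEGORIES",
    "SUBSTANTIVE_CATEGORIES",
    "OTHER_CATEGORY",
    "MappingStatus",
    "ConceptAnnotation",
    "ConceptRecord",
    "RejectionReason",
    "first_stage_filter",
    "default_stopwords",
    "cohen_kappa",
    "AgreementSummary",
    "agreement_table",
    "concept_frequencies",
    "anonymity_filter",
    "MappingSummary",
    "mapping_summary",
    "ConceptInventory",
    "read_annotations_csv",
    "write_concept_records_csv",
]


OTHER_CATEGORY = "Other"
SUBSTANTIVE_CATEGORIES = (
    "Appearance/Behaviour",
    "Speech",
    "Affect/Mood",
    "Thought",
    "Perception",
    "Cognition",
    "Insight",
    "Personality",
)
CATEGORIES = SUBSTANTIVE_CATEGORIES + (OTHER_CATEGORY,)


class MappingStatus(str, Enum):
    """Terminology-mapping outcome for a curated concept."""

    DIRECT = "direct"
    SYNONYM_PARTIAL = "synonym_partial"
    NOVEL = "novel"


@dataclass(frozen=True)
class ConceptAnnotation:
    term: str
    category: str
    annotator: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for term {self.term!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass
class ConceptRecord:
    """One consolidated per-concept report row.

    document_count can never be smaller than patient_count: each
    matching document belongs to exactly one patient.
    """

    term: str
    patient_count: int = 0
    document_count: int = 0
    categories: dict[str, str] = field(default_factory=dict)  # annotator -> category
    mapping_status: MappingStatus | None = None
    snomed_id: str | None = None

    def __post_init__(self) -> None:
        if self.patient_count < 0 or self.document_count < 0:
            raise ValueError("counts cannot be negative")
        if self.document_count < self.patient_count:
            raise ValueError(
                f"{self.term!r}: document_count {self.document_count} < "
                f"patient_count {self.patient_count}"
            )


# --------------------------------------------------------------------------
# First-stage string filtering
# --------------------------------------------------------------------------

class RejectionReason(str, Enum):
    TOKENISATION_FAILURE = "tokenisation-failure"
    STOPWORD_ONLY = "stopword-only"
    NON_WORD = "non-word"


def default_stopwords() -> frozenset[str]:
    ref = resources.files("phenolex.data").joinpath("stopwords.txt")
    words = ref.read_text(encoding="utf-8").split()
    return frozenset(words)


def first_stage_filter(
    terms: Iterable[str], stopwords: frozenset[str] | set[str] | None = None
) -> tuple[list[str], dict[str, RejectionReason]]:
    """Mechanical removal of low-information terms before expert review.

    Removes terms with any single-character token part (tokenisation
    debris such as 'y' or 'p'), terms composed entirely of stop words,
    and terms with no alphabetic character at all.  Returns the retained
    terms and a reason code per removal.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("term list is empty")
    if stopwords is None:
        stopwords = default_stopwords()
    kept: list[str] = []
    removed: dict[str, RejectionReason] = {}
    for term in terms:
        parts = term.split("_")
        if not any(c.isalpha() for c in term):
            removed[term] = RejectionReason.NON_WORD
        elif any(len(p) <= 1 for p in parts):
            removed[term] = RejectionReason.TOKENISATION_FAILURE
        elif all(p in stopwords for p in parts):
            removed[term] = RejectionReason.STOPWORD_ONLY
        else:
            kept.append(term)
    return kept, removed


# --------------------------------------------------------------------------
# Inter-annotator agreement
# --------------------------------------------------------------------------

def _paired_categories(
    a: Mapping[str, str], b: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("annotator term sets are disjoint; nothing to compare")
    return [a[t] for t in shared], [b[t] for t in shared]


def cohen_kappa(a: Mapping[str, str], b: Mapping[str, str]) -> float:
    """Cohen's kappa over the terms both annotators labelled.

    Chance agreement p_e comes from the two marginal category
    distributions.  The degenerate case p_e = 1 (both annotators
    constant and identical) is defined as kappa = 1.
    """
    cats_a, cats_b = _paired_categories(a, b)
    if cats_a == cats_b and len(set(cats_a)) == 1:
        return 1.0
    return float(cohen_kappa_score(cats_a, cats_b))


@dataclass(frozen=True)
class AgreementSummary:
    """Per-category counts of independently agreed terms.

    Label-agnostic by design: any category labelling flows through, and
    everything except the residual Other row counts as substantive.
    """

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def substantive(self) -> int:
        return self.total - self.counts.get(OTHER_CATEGORY, 0)


def agreement_table(a: Mapping[str, str], b: Mapping[str, str]) -> AgreementSummary:
    """Count terms per category where both annotators chose the same label."""
    cats_a, cats_b = _paired_categories(a, b)
    agreed = Counter(ca for ca, cb in zip(cats_a, cats_b) if ca == cb)
    return AgreementSummary(counts=dict(agreed))


# --------------------------------------------------------------------------
# Frequency analysis and anonymity
# --------------------------------------------------------------------------

def concept_frequencies(
    corpus: Corpus, concept_stems: Sequence[str]
) -> list[ConceptRecord]:
    """Unique-patient and unique-document counts per concept stem.

    Stems are matched case-insensitively as substrings of the raw
    document text; underscores in multi-word stems stand for the spaces
    of the original running text.
    """
    lowered = [(doc.patient_id, doc.doc_id, doc.text.lower()) for doc in corpus]
    records = []
    for stem in concept_stems:
        needle = stem.lower().replace("_", " ")
        patients: set[str] = set()
        docs: set[str] = set()
        for patient_id, doc_id, text in lowered:
            if needle in text:
                patients.add(patient_id)
                docs.add(doc_id)
        records.append(
            ConceptRecord(term=stem, patient_count=len(patients), document_count=len(docs))
        )
    return records


def anonymity_filter(
    records: Sequence[ConceptRecord], min_patients: int = 10
) -> list[ConceptRecord]:
    """Drop concepts seen in min_patients or fewer unique patient records.

    The boundary is strict: a concept seen in exactly min_patients
    patients is discarded.
    """
    return [r for r in records if r.patient_count > min_patients]


# --------------------------------------------------------------------------
# Mapping bookkeeping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptInventory:
    """Discovered plus prior concepts carried into curation."""

    discovered: int
    prior: int

    @property
    def total(self) -> int:
        return self.discovered + self.prior


@dataclass(frozen=True)
class MappingSummary:
    direct: int
    synonym_partial: int
    novel: int

    @property
    def total(self) -> int:
        return self.direct + self.synonym_partial + self.novel

    @classmethod
    def from_totals(cls, total: int, direct: int, synonym_partial: int) -> "MappingSummary":
        """Novel (unmapped) count as the remainder of the partition."""
        return cls(direct=direct, synonym_partial=synonym_partial,
                   novel=total - direct - synonym_partial)


def mapping_summary(records: Sequence[ConceptRecord]) -> MappingSummary:
    """Tally mapping outcomes; every record must carry a known status."""
    counts = {status: 0 for status in MappingStatus}
    for r in records:
        if not isinstance(r.mapping_status, MappingStatus):
            raise ValueError(f"{r.term!r}: unknown mapping status {r.mapping_status!r}")
        counts[r.mapping_status] += 1
    return MappingSummary(
        direct=counts[MappingStatus.DIRECT],
        synonym_partial=counts[MappingStatus.SYNONYM_PARTIAL],
        novel=counts[MappingStatus.NOVEL],
    )


# --------------------------------------------------------------------------
# File interfaces
# --------------------------------------------------------------------------

def read_annotations_csv(path: str | Path) -> list[ConceptAnnotation]:
    """Read (term, category, annotator) rows."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ConceptAnnotation(row["term"], row["category"], row["annotator"])
            )
    return out


def write_concept_records_csv(records: Sequence[ConceptRecord], path: str | Path) -> None:
    """Consolidated per-term report (patient/document counts, categories,
    terminology id and mapping status)."""
    annotators = sorted({a for r in records for a in r.categories})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["term", "patient_count", "document_count"]
            + [f"category_{a}" for a in annotators]
            + ["snomed_ct_id", "mapping_status"]
        )
        for r in records:
            writer.writerow(
                [r.term, r.patient_count, r.document_count]
                + [r.categories.get(a, "") for a in annotators]
                + [r.snomed_id or "",
                   r.mapping_status.value if r.mapping_status else ""]
            )
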