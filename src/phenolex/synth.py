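"""Seeded pseudo-clinical corpus generation with planted synonym families.

The generator emulates the statistical structure the discovery pipeline
relies on, not clinical language itself: many short documents per
patient; mental-state-examination-style sentences in which the members
of a symptom synonym family appear inside a shared set of carrier
templates (so the distributional hypothesis can co-locate them); a
Zipfian background vocabulary for filler sentences; fixed adjacent word
pairs for multi-word families (so phrase induction has something to
join); and misspelling noise that preserves the first four characters
of a term (so stem matching still fires on the variants).

A subset of the planted families seeds the prior-concept lexicon; every
other family member is a "discoverable" term the pipeline should pull
into its selected clusters.  Each prior-concept stem also appears
inside a few unrelated background words ("homographs", the way a real
stem like "elat" sits inside "related"); without that word-sense
collision every background cluster would score exactly zero and the
median/MAD selection rule would degenerate.

All randomness flows from a single numpy generator seeded from the
config; no global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cluster import Clustering
from .preprocess import Corpus, Document, Vocabulary

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "RecoveryReport",
    "evaluate_recovery",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_pc_lexicon_tsv",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults describe the reference corpus used throughout the test
    suite: ~2,000 documents over 250 patients, 30 synonym families of
    which 12 seed the prior-concept lexicon.
    """

    n_patients: int = 250
    docs_per_patient_range: tuple[int, int] = (4, 12)
    sentences_per_doc_range: tuple[int, int] = (3, 8)
    n_families: int = 30
    synonyms_per_family_range: tuple[int, int] = (3, 6)
    n_pc_families: int = 12
    background_vocab_size: int = 1500
    zipf_exponent: float = 1.05
    misspelling_rate: float = 0.03
    multiword_family_fraction: float = 0.2
    symptom_sentence_rate: float = 0.35
    homographs_per_pc: int = 3
    seed: int = 1234

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_families", "background_vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "docs_per_patient_range",
            "sentences_per_doc_range",
            "synonyms_per_family_range",
        ):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must satisfy 1 <= min <= max, got {(lo, hi)}")
        for name in (
            "misspelling_rate",
            "multiword_family_fraction",
            "symptom_sentence_rate",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if not 1 <= self.n_pc_families <= self.n_families:
            raise ValueError("need 1 <= n_pc_families <= n_families")
        if self.homographs_per_pc < 0:
            raise ValueError("homographs_per_pc cannot be negative")
        if self.n_patients * self.docs_per_patient_range[0] < 1:
            raise ValueError("expected corpus size is below one document")


@dataclass
class GroundTruth:
    """What was planted: family term sets, the seeded PC lexicon, and the
    discoverable remainder.

    Family terms are phrased surface forms (multi-word terms joined with
    underscores, as the pipeline vocabulary will hold them) and include
    every injected misspelling that was actually emitted.  A term is
    discoverable when no PC pattern occurs inside it.
    """

    families: dict[int, set[str]]
    pc_lexicon: list[tuple[str, str]]  # (concept name, pattern)
    discoverable_terms: set[str] = field(default_factory=set)

    def family_of(self, term: str) -> int | None:
        for fid, terms in self.families.items():
            if term in terms:
                return fid
        return None

    @property
    def all_family_terms(self) -> set[str]:
        return set().union(*self.families.values()) if self.families else set()


# --------------------------------------------------------------------------
# Word and sentence building blocks
# --------------------------------------------------------------------------

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"

# Carrier templates for symptom sentences; {} slots take family terms.
# Mostly single-slot so family identity stays a second-order signal and
# the symptom vocabulary forms one broad context regime.
_TEMPLATES = (
    "patient appears {} today .",
    "on examination there was clear {} .",
    "remains {} at interview .",
    "presented with {} and {} .",
    "mental state examination revealed {} .",
    "ongoing {} noted during review .",
    "staff report {} overnight .",
    "objectively {} throughout the assessment .",
    "no evidence of {} at present .",
    "marked {} observed on the ward .",
    "some {} evident when discussing medication .",
    "reports {} since last week .",
    "presentation dominated by {} and {} .",
    "continues to display {} .",
    "assessment was limited by {} .",
    "improvement in {} compared with admission .",
    "episodes of {} and {} recorded .",
    "notable {} when approached .",
    "denies {} currently .",
    "documented {} during the home visit .",
)

_SUFFIXES = ("ed", "ion", "ing", "ity", "al", "ive")


def _make_word(rng: np.random.Generator, n_syllables: int) -> str:
    out = []
    for _ in range(n_syllables):
        out.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        out.append(_VOWELS[rng.integers(len(_VOWELS))])
    return "".join(out)


def _misspell(term: str, rng: np.random.Generator) -> str:
    """Single-character edit past position 4, first four characters kept."""
    if len(term) < 5:
        return term
    pos = int(rng.integers(4, len(term)))
    op = int(rng.integers(3))
    chars = list(term)
    if op == 0:  # substitution
        alphabet = _CONSONANTS + _VOWELS
        repl = alphabet[rng.integers(len(alphabet))]
        chars[pos] = repl
    elif op == 1:  # deletion
        del chars[pos]
    else:  # adjacent transposition
        if pos == len(term) - 1:
            pos -= 1
        if pos >= 4:
            chars[pos], chars[pos + 1] = chars[pos + 1], chars[pos]
    out = "".join(chars)
    return out if out != term and len(out) >= 5 else term


@dataclass
class _Family:
    fid: int
    multiword: bool
    stem: str              # shared stem (unigram) or canonical bigram head
    base_terms: list[str]  # space-separated surfaces as emitted in text
    pattern: str | None    # set for PC families only


def _build_families(
    config: GeneratorConfig,
    rng: np.random.Generator,
    used_words: set[str],
) -> list[_Family]:
    pc_ids = set(rng.choice(config.n_families, size=config.n_pc_families, replace=False).tolist())
    families: list[_Family] = []
    used_prefixes: set[str] = set()

    def fresh_word(n_syll: int) -> str:
        for _ in range(10_000):
            w = _make_word(rng, n_syll)
            if w in used_words or w[:4] in used_prefixes:
                continue
            used_words.add(w)
            return w
        raise RuntimeError("word space exhausted; reduce vocabulary demands")

    lo, hi = config.synonyms_per_family_range
    for fid in range(config.n_families):
        n_syn = int(rng.integers(lo, hi + 1))
        multiword = bool(rng.random() < config.multiword_family_fraction)
        if multiword:
            head = fresh_word(3)
            used_prefixes.add(head[:4])
            terms = []
            for _ in range(n_syn):
                mod = fresh_word(2 + int(rng.integers(2)))
                used_prefixes.add(mod[:4])
                terms.append(f"{mod} {head}")
            pattern = terms[0].replace(" ", "_") if fid in pc_ids else None
            families.append(_Family(fid, True, head, terms, pattern))
        else:
            stem = fresh_word(3)
            used_prefixes.add(stem[:4])
            n_variants = max(1, (n_syn + 1) // 2)
            terms = []
            for i in range(n_variants):
                suffix = "" if i == 0 else _SUFFIXES[rng.integers(len(_SUFFIXES))]
                cand = stem + suffix
                if cand in terms:
                    continue
                used_words.add(cand)
                terms.append(cand)
            while len(terms) < n_syn:
                w = fresh_word(3 + int(rng.integers(2)))
                used_prefixes.add(w[:4])
                terms.append(w)
            pattern = stem[:4] if fid in pc_ids else None
            families.append(_Family(fid, False, stem, terms, pattern))
    return families


def _build_background(
    config: GeneratorConfig,
    rng: np.random.Generator,
    patterns: list[str],
    forbidden_prefixes: set[str],
    used_words: set[str],
) -> list[str]:
    """Zipf-ranked background words, clean of planted stems except for the
    deliberately injected homographs."""
    unigram_patterns = [p for p in patterns if "_" not in p]
    words: list[str] = []
    seen: set[str] = set(used_words)
    while len(words) < config.background_vocab_size:
        w = _make_word(rng, 2 + int(rng.integers(3)))
        if w in seen or w[:4] in forbidden_prefixes:
            continue
        if any(p in w for p in unigram_patterns):
            continue
        seen.add(w)
        words.append(w)

    homographs: list[str] = []
    for p in unigram_patterns:
        for _ in range(config.homographs_per_pc):
            for _attempt in range(1000):
                w = _make_word(rng, 1) + p + _make_word(rng, 1)
                if w not in seen:
                    seen.add(w)
                    homographs.append(w)
                    break
    # splice homographs into the upper half of the rank order so they stay
    # above the embedding frequency floor
    if homographs:
        upper = max(len(words) // 2, len(homographs))
        step = max(upper // len(homographs), 1)
        for i, w in enumerate(homographs):
            words.insert(min((i + 1) * step, len(words)), w)
    return words


# --------------------------------------------------------------------------
# Corpus emission
# --------------------------------------------------------------------------

def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Emit a seeded corpus and the ground truth planted in it.

    Deterministic for a fixed config (byte-identical documents).  Every
    recorded family term was emitted at least once; a PC pattern whose
    matching terms were never emitted (possible only for tiny configs)
    is dropped from the lexicon rather than left dangling.
    """
    rng = np.random.default_rng(config.seed)
    used_words: set[str] = set()
    families = _build_families(config, rng, used_words)
    patterns = [f.pattern for f in families if f.pattern is not None]
    prefixes = {f.stem[:4] for f in families}
    background = _build_background(config, rng, patterns, prefixes, used_words)

    ranks = np.arange(1, len(background) + 1, dtype=np.float64)
    zipf_p = ranks ** -config.zipf_exponent
    zipf_p /= zipf_p.sum()
    zipf_cdf = np.cumsum(zipf_p)

    emitted: dict[int, set[str]] = {f.fid: set() for f in families}
    docs: list[Document] = []
    d_lo, d_hi = config.docs_per_patient_range
    s_lo, s_hi = config.sentences_per_doc_range
    doc_serial = 0

    def draw_symptom_surface(fam: _Family) -> str:
        term = fam.base_terms[int(rng.integers(len(fam.base_terms)))]
        if config.misspelling_rate > 0 and rng.random() < config.misspelling_rate:
            if fam.multiword:
                mod, head = term.split(" ")
                if rng.random() < 0.5:
                    mod = _misspell(mod, rng)
                else:
                    head = _misspell(head, rng)
                term = f"{mod} {head}"
            else:
                term = _misspell(term, rng)
        emitted[fam.fid].add(term.replace(" ", "_"))
        return term

    for p in range(config.n_patients):
        patient_id = f"p{p:05d}"
        n_docs = int(rng.integers(d_lo, d_hi + 1))
        for _ in range(n_docs):
            sentences = []
            for _ in range(int(rng.integers(s_lo, s_hi + 1))):
                if rng.random() < config.symptom_sentence_rate:
                    fam = families[int(rng.integers(len(families)))]
                    template = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
                    n_slots = template.count("{}")
                    fills = [draw_symptom_surface(fam) for _ in range(n_slots)]
                    sentences.append(template.format(*fills))
                else:
                    length = int(rng.integers(5, 13))
                    idx = np.searchsorted(zipf_cdf, rng.random(length))
                    sentences.append(" ".join(background[i] for i in idx) + " .")
            docs.append(Document(patient_id, f"d{doc_serial:07d}", " ".join(sentences)))
            doc_serial += 1

    # lexicon entries whose pattern is present in at least one emitted term
    all_emitted = set().union(*emitted.values()) if emitted else set()
    lexicon: list[tuple[str, str]] = []
    for fam in families:
        if fam.pattern is None:
            continue
        if any(fam.pattern in t for t in all_emitted):
            canonical = fam.base_terms[0].replace(" ", "_")
            lexicon.append((canonical, fam.pattern))
    kept_patterns = [p for _, p in lexicon]
    discoverable = {
        t for t in all_emitted if not any(p in t for p in kept_patterns)
    }
    truth = GroundTruth(
        families={fid: terms for fid, terms in emitted.items()},
        pc_lexicon=lexicon,
        discoverable_terms=discoverable,
    )
    return Corpus(docs), truth


# --------------------------------------------------------------------------
# Recovery evaluation
# --------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """How much of the planted discoverable vocabulary the selection found."""

    recovery: float
    n_eligible: int
    n_recovered: int
    per_family: dict[int, tuple[int, int]]  # fid -> (recovered, eligible)
    background_selected: int
    empty_selection: bool = False


def evaluate_recovery(
    clustering: Clustering,
    selected: Sequence[int],
    truth: GroundTruth,
    vocab: Vocabulary,
) -> RecoveryReport:
    """Fraction of discoverable planted terms that the selection captured.

    Eligible terms are discoverable terms present both in the phrased
    vocabulary and in the clustered (frequency-filtered) term set —
    terms the embedding never saw cannot be recovered by any selection.
    Background terms inside the selection (anything not belonging to a
    planted family) are counted as the cost of the trawl.
    """
    clustered = set(clustering.terms)
    eligible = {
        t for t in truth.discoverable_terms if t in vocab and t in clustered
    }
    selected_set = set(int(j) for j in selected)
    selected_terms = {
        t for t, c in zip(clustering.terms, clustering.labels) if int(c) in selected_set
    }
    if not selected_set:
        return RecoveryReport(
            recovery=0.0,
            n_eligible=len(eligible),
            n_recovered=0,
            per_family={fid: (0, len(terms & eligible)) for fid, terms in truth.families.items()},
            background_selected=0,
            empty_selection=True,
        )
    recovered = eligible & selected_terms
    per_family = {}
    for fid, terms in truth.families.items():
        fam_eligible = terms & eligible
        per_family[fid] = (len(fam_eligible & recovered), len(fam_eligible))
    family_terms = truth.all_family_terms
    background_selected = sum(1 for t in selected_terms if t not in family_terms)
    recovery = len(recovered) / len(eligible) if eligible else 0.0
    return RecoveryReport(
        recovery=recovery,
        n_eligible=len(eligible),
        n_recovered=len(recovered),
        per_family=per_family,
        background_selected=background_selected,
    )


# --------------------------------------------------------------------------
# Serialisation
# --------------------------------------------------------------------------

def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "families": {str(fid): sorted(terms) for fid, terms in truth.families.items()},
        "pc_lexicon": [list(pair) for pair in truth.pc_lexicon],
        "discoverable_terms": sorted(truth.discoverable_terms),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        families={int(fid): set(terms) for fid, terms in payload["families"].items()},
        pc_lexicon=[tuple(pair) for pair in payload["pc_lexicon"]],
        discoverable_terms=set(payload["discoverable_terms"]),
    )


def write_pc_lexicon_tsv(truth: GroundTruth, path: str | Path) -> None:
    """Same TSV dialect the scoring module reads back."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concept\tpattern\n")
        for concept, pattern in truth.pc_lexicon:
            fh.write(f"{concept}\t{pattern}\n")
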