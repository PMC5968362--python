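"""CBOW word embeddings over a phrased corpus.

The trainer is a compact continuous-bag-of-words implementation with
negative sampling: a term is predicted from the average of its
within-sentence context vectors, and the input matrix W (one row of
n weights per vocabulary term) is the embedding that comes out.
Sentences are the context unit — windows never cross sentence
boundaries.  Training is single-threaded and fully driven by one seeded
generator, so a fixed seed reproduces the vectors bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EmbeddingParams",
    "EmbeddingModel",
    "train_cbow",
    "cosine_similarity",
    "nearest_neighbours",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Training knobs for the CBOW model.

    n is the embedding dimension (the hidden-layer width); window is the
    context half-width in tokens within a sentence; min_count drops rare
    terms before training; negative is the number of noise samples per
    prediction; alpha decays linearly to min_alpha over training.
    """

    n: int = 100
    window: int = 5
    epochs: int = 1
    min_count: int = 5
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"embedding dimension must be >= 2, got {self.n}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {self.min_count}")
        if self.negative < 1:
            raise ValueError(f"negative must be >= 1, got {self.negative}")


class EmbeddingModel:
    """Term -> n-dimensional vector map (the trained input matrix W)."""

    def __init__(self, terms: list[str], vectors: np.ndarray):
        if vectors.shape[0] != len(terms):
            raise ValueError("one vector per term required")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("embedding vectors must be finite")
        self.terms = list(terms)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self.index = {t: i for i, t in enumerate(self.terms)}

    @property
    def n(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.vectors[self.index[term]]
        except KeyError:
            raise KeyError(f"term not in embedding model: {term!r}") from None

    def save_word2vec(self, path: str | Path) -> None:
        """Persist in the word2vec text format: header 'o n', then rows."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.terms)} {self.n}\n")
            for term, vec in zip(self.terms, self.vectors):
                fh.write(term + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            o, n = map(int, fh.readline().split())
            terms, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != n + 1:
                    raise ValueError(f"malformed vector row for {parts[0]!r}")
                terms.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(terms) != o:
            raise ValueError(f"header announced {o} terms, found {len(terms)}")
        return cls(terms, np.array(rows))


def _flatten(corpus) -> list[list[str]]:
    """Accept a per-document sentence structure or a flat sentence list."""
    if corpus and corpus[0] and isinstance(corpus[0][0], list):
        return [sent for doc in corpus for sent in doc]
    return list(corpus)


def train_cbow(corpus, params: EmbeddingParams = EmbeddingParams()) -> EmbeddingModel:
    """Train CBOW with negative sampling over tokenised, phrased sentences.

    The model vocabulary is exactly the set of corpus terms with
    frequency >= params.min_count, ordered by descending frequency
    (ties broken alphabetically).  Raises ValueError if nothing
    survives the frequency filter.
    """
    sentences = _flatten(corpus)
    if not sentences:
        raise ValueError("cannot train on an empty corpus")

    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = [t for t, c in counts.items() if c >= params.min_count]
    if not vocab:
        raise ValueError(
            f"no term reaches min_count={params.min_count}; corpus too small"
        )
    vocab.sort(key=lambda t: (-counts[t], t))
    index = {t: i for i, t in enumerate(vocab)}
    o, n = len(vocab), params.n

    rng = np.random.default_rng(params.seed)
    w_in = (rng.random((o, n)) - 0.5) / n  # the W matrix: the embedding
    w_out = np.zeros((o, n))               # the W' matrix: prediction weights

    # unigram^0.75 noise distribution, sampled through a flat table
    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())

    encoded = [
        np.array([index[t] for t in sent if t in index], dtype=np.int64)
        for sent in sentences
    ]
    encoded = [s for s in encoded if len(s) >= 2]
    if not encoded:
        raise ValueError("no sentence retains two in-vocabulary tokens")

    total_centres = params.epochs * sum(len(s) for s in encoded)
    alpha_span = params.alpha - params.min_alpha
    window, negative = params.window, params.negative

    seen = 0
    neg_pool = np.searchsorted(noise_cdf, rng.random(1 << 16))
    pool_pos = 0
    for _ in range(params.epochs):
        for sent in encoded:
            ln = len(sent)
            for pos in range(ln):
                lo = max(0, pos - window)
                hi = min(ln, pos + window + 1)
                ctx = np.concatenate((sent[lo:pos], sent[pos + 1 : hi]))
                if ctx.size == 0:
                    seen += 1
                    continue
                alpha = params.alpha - alpha_span * (seen / total_centres)
                if pool_pos + negative > neg_pool.size:
                    neg_pool = np.searchsorted(noise_cdf, rng.random(1 << 16))
                    pool_pos = 0
                targets = np.empty(negative + 1, dtype=np.int64)
                targets[0] = sent[pos]
                targets[1:] = neg_pool[pool_pos : pool_pos + negative]
                pool_pos += negative

                h = w_in[ctx].mean(axis=0)
                f = 1.0 / (1.0 + np.exp(-(w_out[targets] @ h)))
                g = -f * alpha
                g[0] += alpha  # positive label on the true centre word
                err = g @ w_out[targets]
                w_out[targets] += np.outer(g, h)
                w_in[ctx] += err
                seen += 1

    return EmbeddingModel(vocab, w_in)


def cosine_similarity(model: EmbeddingModel, a: str, b: str) -> float:
    """Cosine of the angle between two term vectors; in [-1, 1]."""
    va, vb = model.vector(a), model.vector(b)
    denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
    if denom == 0.0:
        return 0.0
    return float(np.dot(va, vb) / denom)


def nearest_neighbours(
    model: EmbeddingModel, term: str, top_n: int = 10
) -> list[tuple[str, float]]:
    """Terms ranked by descending cosine similarity, query excluded."""
    qi = model.index.get(term)
    if qi is None:
        raise KeyError(f"term not in embedding model: {term!r}")
    if top_n <= 0:
        return []
    v = model.vectors[qi]
    norms = np.linalg.norm(model.vectors, axis=1)
    nv = float(np.linalg.norm(v))
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = (model.vectors @ v) / (norms * nv)
    sims = np.nan_to_num(sims, nan=0.0)
    order = [i for i in np.argsort(-sims, kind="stable") if i != qi]
    return [(model.terms[i], float(sims[i])) for i in order[:top_n]]
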