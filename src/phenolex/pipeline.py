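"""End-to-end discovery run: corpus -> phrases -> embedding -> clusters ->
relevance scores -> selected vocabulary.

Glue only; every step lives in its own module.  The defaults reproduce
the reference synthetic study the test suite exercises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import cluster as _cluster
from . import embed as _embed
from . import preprocess as _pre
from . import score as _score
from . import synth as _synth

__all__ = ["DiscoveryResult", "run_discovery", "DEFAULT_K_GRID"]

DEFAULT_K_GRID = (2, 4, 6, 8, 10, 12, 14, 16, 20, 24, 28)


@dataclass
class DiscoveryResult:
    corpus: _pre.Corpus
    truth: _synth.GroundTruth
    phrase_model: _pre.PhraseModel
    vocabulary: _pre.Vocabulary
    model: _embed.EmbeddingModel
    elbow: _cluster.ElbowCurve
    suggested_k: _cluster.SuggestedK
    clustering: _cluster.Clustering
    count_matrix: _score.CountMatrix
    score_table: _score.ScoreTable
    recovery: _synth.RecoveryReport


def run_discovery(
    config: _synth.GeneratorConfig | None = None,
    *,
    embedding: _embed.EmbeddingParams | None = None,
    phrase_min_count: int = 10,
    phrase_threshold: float = 10.0,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    k: int | None = None,
    flatten_tolerance: float = 0.25,
    mad_multiplier: float = 6.0,
    seed: int | None = None,
) -> DiscoveryResult:
    """Run the whole pipeline on a generated corpus.

    `seed`, when given, overrides both the generator seed and the
    embedding/clustering seeds so one integer pins the entire run.
    An explicit `k` bypasses the elbow suggestion (the scan still runs
    so the curve is reported).
    """
    if config is None:
        config = _synth.GeneratorConfig()
    if seed is not None:
        config = _synth.GeneratorConfig(
            **{**config.__dict__, "seed": seed}
        )
    if embedding is None:
        # a desk-scale corpus needs several passes to accumulate the update
        # volume a production corpus delivers in one
        embedding = _embed.EmbeddingParams(n=50, epochs=10, seed=config.seed + 1)

    corpus, truth = _synth.generate_corpus(config)
    tokenised = _pre.tokenize_corpus(corpus)
    flat = [s for doc in tokenised for s in doc]
    phrase_model = _pre.learn_phrases(
        flat, min_count=phrase_min_count, threshold=phrase_threshold
    )
    phrased = _pre.phrase_corpus(tokenised, phrase_model)
    vocabulary = _pre.build_vocabulary(phrased)

    model = _embed.train_cbow(phrased, embedding)

    cluster_seed = config.seed + 2
    elbow = _cluster.elbow_scan(model, list(k_grid), seed=cluster_seed)
    suggestion = _cluster.suggest_k(elbow, flatten_tolerance=flatten_tolerance)
    chosen_k = k if k is not None else suggestion.k
    clustering = _cluster.cluster_terms(model, chosen_k, seed=cluster_seed)

    pcs = [_score.PriorConcept(name, pattern) for name, pattern in truth.pc_lexicon]
    cm = _score.rescale_matrix(_score.count_pc_hits(clustering, pcs))
    table = _score.select_clusters(
        _score.score_clusters(cm, clustering.sizes), multiplier=mad_multiplier
    )
    recovery = _synth.evaluate_recovery(clustering, table.selected, truth, vocabulary)

    return DiscoveryResult(
        corpus=corpus,
        truth=truth,
        phrase_model=phrase_model,
        vocabulary=vocabulary,
        model=model,
        elbow=elbow,
        suggested_k=suggestion,
        clustering=clustering,
        count_matrix=cm,
        score_table=table,
        recovery=recovery,
    )
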