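"""k-means partitioning of embedding vectors and elbow-based k selection.

Pairwise-distance clustering methods need O(n^2) memory, which rules
them out for vocabularies of this size; k-means++ with restarts is the
scalable alternative.  Because the within-cluster error always falls as
k grows, k is chosen from the minimum pairwise centroid distance curve:
genuine structure keeps centroids apart, and the curve's decline
flattens once extra clusters start splitting noise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .embed import EmbeddingModel

__all__ = [
    "Clustering",
    "ElbowCurve",
    "SuggestedK",
    "cluster_terms",
    "min_centroid_distance",
    "elbow_scan",
    "suggest_k",
]


@dataclass
class Clustering:
    """A hard partition of embedding terms into k clusters."""

    terms: list[str]
    labels: np.ndarray          # cluster id per term, in [0, k)
    centroids: np.ndarray       # k x n
    k: int
    inertia: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if len(self.terms) != len(self.labels):
            raise ValueError("one label per term required")

    @property
    def sizes(self) -> np.ndarray:
        """Member count s_j per cluster id."""
        return np.bincount(self.labels, minlength=self.k)

    @property
    def assignment(self) -> dict[str, int]:
        return {t: int(c) for t, c in zip(self.terms, self.labels)}

    def members(self, cluster_id: int) -> list[str]:
        return [t for t, c in zip(self.terms, self.labels) if c == cluster_id]

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tcluster_id\n")
            for t, c in zip(self.terms, self.labels):
                fh.write(f"{t}\t{int(c)}\n")


def cluster_terms(
    model: EmbeddingModel,
    k: int,
    n_init: int = 8,
    seed: int = 0,
    normalise: bool = False,
) -> Clustering:
    """Partition the model's vectors with k-means++ and restarts.

    Runs n_init independent seeded k-means++ fits and keeps the one with
    the lowest inertia (ties go to the lowest restart index, so a fixed
    seed always reproduces the same partition).  Vectors are clustered
    raw by default; normalise=True unit-normalises rows first.
    """
    n_terms = len(model)
    if k < 2 or k > n_terms:
        raise ValueError(f"k must be in [2, {n_terms}], got {k}")
    X = model.vectors
    if normalise:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        X = X / norms

    best: KMeans | None = None
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_init)
    for rs in restart_seeds:
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=int(rs))
        km.fit(X)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    assert best is not None
    return Clustering(
        terms=list(model.terms),
        labels=best.labels_.astype(np.int64),
        centroids=best.cluster_centers_.astype(np.float64),
        k=k,
        inertia=float(best.inertia_),
    )


def min_centroid_distance(clustering: Clustering) -> float:
    """Smallest Euclidean distance between any two centroids.

    Undefined for a single cluster, hence the k >= 2 requirement.
    """
    if clustering.k < 2:
        raise ValueError("minimum centroid distance requires k >= 2")
    return float(pdist(clustering.centroids).min())


@dataclass
class ElbowCurve:
    """(k, minimum centroid distance) points at strictly increasing k."""

    points: list[tuple[int, float]]

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.points]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k values must be strictly increasing")
        if any(d < 0 for _, d in self.points):
            raise ValueError("centroid distances cannot be negative")

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["k", "min_centroid_distance"])
            writer.writerows(self.points)


def elbow_scan(
    model: EmbeddingModel,
    k_values: Sequence[int],
    seed: int = 0,
    n_init: int = 8,
    normalise: bool = False,
) -> ElbowCurve:
    """Full cluster_terms run per k; records each minimum centroid distance."""
    points = []
    for k in k_values:
        clustering = cluster_terms(model, k, n_init=n_init, seed=seed, normalise=normalise)
        points.append((int(k), min_centroid_distance(clustering)))
    return ElbowCurve(points)


class SuggestedK(NamedTuple):
    k: int
    no_elbow: bool  # set when the decline never flattens within the scan


def suggest_k(curve: ElbowCurve, flatten_tolerance: float = 0.05) -> SuggestedK:
    """Smallest k after which the curve's relative decline stays flat.

    A point qualifies when every later step's relative decrease in
    minimum centroid distance falls below flatten_tolerance.  If the
    decline is still steep at the end of the scan there is no elbow:
    the largest scanned k is returned with the no_elbow flag raised.
    The caller may always override with an explicit k chosen by eye.
    """
    if len(curve.points) < 3:
        raise ValueError("elbow suggestion requires at least 3 curve points")
    dists = [d for _, d in curve.points]
    rel_drops = [
        (d0 - d1) / d0 if d0 > 0 else 0.0 for d0, d1 in zip(dists, dists[1:])
    ]
    for i in range(len(curve.points) - 1):
        if all(drop < flatten_tolerance for drop in rel_drops[i:]):
            return SuggestedK(k=curve.points[i][0], no_elbow=False)
    return SuggestedK(k=curve.points[-1][0], no_elbow=True)
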