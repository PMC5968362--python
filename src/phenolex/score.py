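"""Prior-concept cluster relevance scoring and robust cluster selection.

A small lexicon of known symptom stems ("prior concepts", PCs) is
matched against every clustered term to build a count matrix x, with
x[i, j] the number of cluster-j terms containing PC i.  Each PC row is
min–max rescaled to [0, 1] so that no frequent stem dominates, the
rescaled counts are summed per cluster and divided by cluster size, and
clusters scoring at least `multiplier` median-absolute-deviations above
the median score are selected.  The MAD is used unscaled (no
normal-consistency constant): cluster score distributions are far from
normal, and the robust statistic is the point.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .cluster import Clustering

__all__ = [
    "PriorConcept",
    "load_pc_lexicon",
    "default_pc_lexicon",
    "CountMatrix",
    "count_pc_hits",
    "rescale_matrix",
    "ScoreTable",
    "score_clusters",
    "mad",
    "mad_threshold",
    "select_clusters",
]


@dataclass(frozen=True)
class PriorConcept:
    """A known symptom concept and its literal matching stem.

    An underscore in the pattern spans an induced n-gram boundary, so
    multi-word stems match the phrased vocabulary (e.g. ``eye_contact``).
    """

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"PC {self.name!r}: empty pattern")
        if self.pattern != self.pattern.lower():
            raise ValueError(f"PC {self.name!r}: pattern must be lowercase")
        if any(c.isspace() for c in self.pattern):
            raise ValueError(f"PC {self.name!r}: pattern contains whitespace")


def load_pc_lexicon(path: str | Path) -> list[PriorConcept]:
    """Read a (concept, pattern) TSV; validates rows and rejects duplicates."""
    pcs: list[PriorConcept] = []
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "concept\tpattern":
            raise ValueError(f"line 1: expected header 'concept\\tpattern', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated fields")
            name, pattern = parts
            if pattern in seen:
                raise ValueError(
                    f"line {lineno}: duplicate pattern {pattern!r} (first on line {seen[pattern]})"
                )
            seen[pattern] = lineno
            try:
                pcs.append(PriorConcept(name, pattern))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return pcs


def default_pc_lexicon() -> list[PriorConcept]:
    """The packaged serious-mental-illness symptom lexicon (38 concepts)."""
    ref = resources.files("phenolex.data").joinpath("pc_lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_pc_lexicon(path)


@dataclass
class CountMatrix:
    """PC-by-cluster hit counts and their min–max rescaling.

    x[i, j] counts cluster-j terms containing PC i; u and v are the
    per-PC row minima and maxima; x_prime is (x - u) / (v - u), with
    constant rows (v == u, an uninformative PC) defined as all zero.
    """

    pcs: list[PriorConcept]
    x: np.ndarray
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    x_prime: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.x.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.x.shape[1]


def count_pc_hits(clustering: Clustering, pcs: Sequence[PriorConcept]) -> CountMatrix:
    """Build the m x k hit-count matrix by literal-stem matching.

    Matching is case-insensitive substring containment, compiled as
    literal regular expressions; a term containing two PC stems
    increments both rows.
    """
    if not pcs:
        raise ValueError("PC lexicon is empty")
    if clustering.k < 1 or not clustering.terms:
        raise ValueError("clustering is empty")
    patterns = [re.compile(re.escape(pc.pattern), re.IGNORECASE) for pc in pcs]
    x = np.zeros((len(pcs), clustering.k), dtype=np.int64)
    for term, cid in zip(clustering.terms, clustering.labels):
        for i, pat in enumerate(patterns):
            if pat.search(term):
                x[i, cid] += 1
    return CountMatrix(pcs=list(pcs), x=x)


def rescale_matrix(cm: CountMatrix) -> CountMatrix:
    """Fill u, v and the [0, 1]-rescaled matrix x_prime in place."""
    x = cm.x
    u = x.min(axis=1)
    v = x.max(axis=1)
    span = (v - u).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_prime = (x - u[:, None]) / span[:, None]
    x_prime[span == 0, :] = 0.0  # a PC with equal counts everywhere says nothing
    cm.u, cm.v, cm.x_prime = u, v, x_prime
    return cm


@dataclass
class ScoreTable:
    """Per-cluster relevance scores z and the MAD selection that follows."""

    z: np.ndarray
    sizes: np.ndarray
    median_score: float = field(default=float("nan"))
    mad_score: float = field(default=float("nan"))
    multiplier: float = 6.0
    threshold: float = field(default=float("nan"))
    selected: list[int] = field(default_factory=list)
    degenerate_mad: bool = False

    @property
    def selected_term_total(self) -> int:
        """Combined size of the selected clusters."""
        return int(self.sizes[self.selected].sum())

    def save(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        with open(csv_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cluster_id", "size", "z", "selected"])
            sel = set(self.selected)
            for j, (zj, sj) in enumerate(zip(self.z, self.sizes)):
                writer.writerow([j, int(sj), f"{zj:.6g}", int(j in sel)])
        if sidecar_path is not None:
            meta = {
                "median": self.median_score,
                "mad": self.mad_score,
                "multiplier": self.multiplier,
                "threshold": self.threshold,
                "degenerate_mad": self.degenerate_mad,
            }
            Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def score_clusters(cm: CountMatrix, sizes: Sequence[int] | np.ndarray) -> ScoreTable:
    """z_j = (sum_i x'_{i,j}) / s_j — size-normalised rescaled PC mass.

    Dividing by the cluster size removes the advantage big clusters
    would otherwise gain just by holding more terms.
    """
    if cm.x_prime is None:
        raise ValueError("rescale_matrix must run before scoring")
    s = np.asarray(sizes, dtype=np.float64)
    if s.shape[0] != cm.n_clusters:
        raise ValueError("one size per cluster required")
    if np.any(s <= 0):
        raise ValueError("cluster sizes must be positive; got an empty cluster")
    z = cm.x_prime.sum(axis=0) / s
    return ScoreTable(z=z, sizes=np.asarray(sizes, dtype=np.int64))


def mad(values: Sequence[float] | np.ndarray) -> float:
    """Median absolute deviation from the median, unscaled."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("MAD of an empty sequence is undefined")
    return float(np.median(np.abs(arr - np.median(arr))))


def mad_threshold(median: float, mad_value: float, multiplier: float = 6.0) -> float:
    """Selection cut-off: median + multiplier x MAD."""
    return median + multiplier * mad_value


def select_clusters(table: ScoreTable, multiplier: float = 6.0) -> ScoreTable:
    """Select clusters scoring at least `multiplier` MADs above the median.

    When the score MAD is zero the threshold collapses onto the median
    and the rule degenerates: clusters strictly above the median are
    selected; if no cluster rises above it (all scores tied) every
    cluster is selected.  Either way the degenerate_mad flag is raised
    so callers can treat the selection with suspicion.
    """
    z = table.z
    med = float(np.median(z))
    spread = mad(z)
    table.median_score = med
    table.mad_score = spread
    table.multiplier = float(multiplier)
    if spread == 0.0:
        table.degenerate_mad = True
        table.threshold = med
        above = np.nonzero(z > med)[0]
        if above.size == 0:
            above = np.nonzero(z >= med)[0]
        table.selected = [int(j) for j in above]
    else:
        table.degenerate_mad = False
        table.threshold = mad_threshold(med, spread, multiplier)
        table.selected = [int(j) for j in np.nonzero(z >= table.threshold)[0]]
    return table
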