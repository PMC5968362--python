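"""Prior-concept counting, min-max rescaling, cluster scores, MAD selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phenolex.cluster import Clustering
from phenolex.score import (
    CountMatrix,
    PriorConcept,
    count_pc_hits,
    default_pc_lexicon,
    load_pc_lexicon,
    mad,
    mad_threshold,
    rescale_matrix,
    score_clusters,
    select_clusters,
)


def _toy_clustering(term_to_cluster):
    terms = list(term_to_cluster)
    labels = np.array([term_to_cluster[t] for t in terms])
    k = int(labels.max()) + 1
    return Clustering(
        terms=terms,
        labels=labels,
        centroids=np.zeros((k, 2)),
        k=k,
        inertia=0.0,
    )


# --------------------------------------------------------------------------
# Lexicon loading
# --------------------------------------------------------------------------

def test_packaged_lexicon_loads():
    pcs = default_pc_lexicon()
    patterns = {pc.pattern for pc in pcs}
    assert "agitat" in patterns
    assert "eye_contact" in patterns
    assert "agitat" in "agitated"


def test_lexicon_validation(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("concept\tpattern\nagitation\t\n")
    with pytest.raises(ValueError, match="line 2"):
        load_pc_lexicon(bad)
    dup = tmp_path / "dup.tsv"
    dup.write_text("concept\tpattern\na\tfoo\nb\tfoo\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_pc_lexicon(dup)
    malformed = tmp_path / "malformed.tsv"
    malformed.write_text("concept\tpattern\nonly-one-field\n")
    with pytest.raises(ValueError, match="line 2"):
        load_pc_lexicon(malformed)


def test_prior_concept_invariants():
    with pytest.raises(ValueError):
        PriorConcept("x", "")
    with pytest.raises(ValueError):
        PriorConcept("x", "Upper")
    with pytest.raises(ValueError):
        PriorConcept("x", "a b")


# --------------------------------------------------------------------------
# Hit counting
# --------------------------------------------------------------------------

def test_insomnia_variants_count_twice():
    clustering = _toy_clustering({"insomnia": 0, "insomniac": 0, "sleep": 1})
    cm = count_pc_hits(clustering, [PriorConcept("insomnia", "insomni")])
    assert cm.x.tolist() == [[2, 0]]


def test_cluster_without_matches_gives_zero_column():
    clustering = _toy_clustering({"apathy": 0, "unrelated": 1})
    cm = count_pc_hits(clustering, [PriorConcept("apathy", "apath")])
    assert cm.x[:, 1].tolist() == [0]


def test_count_pc_hits_matches_substring_scan():
    rng = np.random.default_rng(11)
    alphabet = ["ag", "it", "at", "ap", "ha", "lu", "xo"]
    terms = {
        "".join(rng.choice(alphabet, size=rng.integers(2, 5))): int(rng.integers(4))
        for _ in range(60)
    }
    clustering = _toy_clustering({**terms, "pad0": 0, "pad1": 1, "pad2": 2, "pad3": 3})
    pcs = [PriorConcept("a", "agit"), PriorConcept("b", "halu"), PriorConcept("c", "xo")]
    cm = count_pc_hits(clustering, pcs)
    brute = np.zeros((3, clustering.k), dtype=int)
    for term, cid in zip(clustering.terms, clustering.labels):
        for i, pc in enumerate(pcs):
            if pc.pattern in term:
                brute[i, cid] += 1
    np.testing.assert_array_equal(cm.x, brute)


# --------------------------------------------------------------------------
# Rescaling
# --------------------------------------------------------------------------

def test_rescale_hand_example():
    cm = CountMatrix(pcs=[], x=np.array([[2, 0], [0, 1]]))
    rescale_matrix(cm)
    np.testing.assert_array_equal(cm.u, [0, 0])
    np.testing.assert_array_equal(cm.v, [2, 1])
    np.testing.assert_allclose(cm.x_prime, [[1.0, 0.0], [0.0, 1.0]])


def test_rescale_constant_row_is_zero():
    cm = rescale_matrix(CountMatrix(pcs=[], x=np.array([[3, 3, 3]])))
    np.testing.assert_array_equal(cm.x_prime, [[0.0, 0.0, 0.0]])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    arrays(
        dtype=np.int64,
        shape=st.tuples(st.integers(1, 6), st.integers(2, 8)),
        elements=st.integers(0, 50),
    )
)
def test_rescale_bounds_and_extremes(x):
    cm = rescale_matrix(CountMatrix(pcs=[], x=x))
    assert np.all(cm.x_prime >= 0.0) and np.all(cm.x_prime <= 1.0)
    for i in range(x.shape[0]):
        assert cm.u[i] == x[i].min() and cm.v[i] == x[i].max()
        if x[i].max() > x[i].min():
            assert cm.x_prime[i].max() == pytest.approx(1.0)
            assert cm.x_prime[i].min() == pytest.approx(0.0)


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------

def _scored(x, sizes):
    cm = rescale_matrix(CountMatrix(pcs=[], x=np.asarray(x)))
    return score_clusters(cm, sizes)


def test_score_hand_example():
    table = _scored([[2, 0], [0, 1]], [4, 5])
    np.testing.assert_allclose(table.z, [0.25, 0.2])


def test_all_zero_matrix_scores_zero():
    table = _scored([[0, 0], [0, 0]], [3, 7])
    np.testing.assert_array_equal(table.z, [0.0, 0.0])


def test_score_halves_when_size_doubles():
    a = _scored([[2, 0], [0, 1]], [4, 5])
    b = _scored([[2, 0], [0, 1]], [8, 5])
    assert b.z[0] == pytest.approx(a.z[0] / 2)


def test_zero_cluster_size_rejected():
    cm = rescale_matrix(CountMatrix(pcs=[], x=np.array([[1, 0]])))
    with pytest.raises(ValueError):
        score_clusters(cm, [0, 5])


def test_score_requires_rescaled_matrix():
    with pytest.raises(ValueError):
        score_clusters(CountMatrix(pcs=[], x=np.array([[1, 0]])), [1, 1])


def test_score_bounds():
    rng = np.random.default_rng(17)
    for _ in range(20):
        m, k = int(rng.integers(1, 8)), int(rng.integers(2, 9))
        x = rng.integers(0, 20, size=(m, k))
        sizes = rng.integers(1, 30, size=k)
        table = _scored(x, sizes)
        assert np.all(table.z >= 0)
        assert np.all(table.z <= m / sizes + 1e-12)


def test_additive_inflation_of_one_pc_changes_nothing():
    """Min-max rescaling removes any constant inflation of a PC's hit
    counts, so an over-represented stem cannot dominate the scores."""
    rng = np.random.default_rng(23)
    for _ in range(20):
        x = rng.integers(0, 10, size=(4, 6))
        sizes = rng.integers(1, 20, size=6)
        base = select_clusters(_scored(x, sizes))
        inflated = x.copy()
        inflated[2] += 17
        boosted = select_clusters(_scored(inflated, sizes))
        np.testing.assert_allclose(base.z, boosted.z)
        assert base.selected == boosted.selected


def test_permutation_equivariance():
    rng = np.random.default_rng(29)
    x = rng.integers(0, 10, size=(5, 7))
    sizes = rng.integers(1, 20, size=7)
    perm = rng.permutation(7)
    base = select_clusters(_scored(x, sizes))
    permuted = select_clusters(_scored(x[:, perm], sizes[perm]))
    np.testing.assert_allclose(permuted.z, base.z[perm])
    assert sorted(permuted.selected) == sorted(
        int(np.where(perm == j)[0][0]) for j in base.selected
    )


# --------------------------------------------------------------------------
# MAD and selection
# --------------------------------------------------------------------------

def test_mad_values():
    assert mad([5.0, 5.0, 5.0]) == 0.0
    assert mad([1, 2, 3, 4, 5]) == 1.0
    with pytest.raises(ValueError):
        mad([])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
def test_mad_matches_definition(values):
    arr = sorted(values)
    n = len(arr)
    med = arr[n // 2] if n % 2 else (arr[n // 2 - 1] + arr[n // 2]) / 2
    devs = sorted(abs(v - med) for v in arr)
    brute = devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2
    assert mad(values) == pytest.approx(brute)


def test_single_outlier_selected():
    table = _scored([[0] * 9 + [1]], [1] * 10)
    table = select_clusters(table, multiplier=6)
    assert table.selected == [9]
    assert table.degenerate_mad  # MAD of nine zeros and a one is zero


def test_degenerate_mad_selects_all_with_warning():
    table = _scored([[1, 1], [1, 1]], [2, 2])
    table = select_clusters(table)
    assert table.degenerate_mad
    assert table.selected == [0, 1]


def test_threshold_is_median_plus_multiplier_mad():
    assert mad_threshold(0.5, 0.1, 6) == pytest.approx(1.1)
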