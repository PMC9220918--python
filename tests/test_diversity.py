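import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from rarephylo.diversity import (
    alpha_diversity,
    beta_diversity,
    geographic_distances,
    mantel,
    rarefy,
    upgma,
)
from rarephylo.io import CommunityTable, SampleMetadata


# -- rarefaction --------------------------------------------------------------

def make_table(rows, sample_ids=None, asv_ids=None):
    rows = np.atleast_2d(np.asarray(rows))
    return CommunityTable(
        rows,
        sample_ids or [f"S{i}" for i in range(rows.shape[0])],
        asv_ids or [f"A{j}" for j in range(rows.shape[1])],
    )


def test_rarefy_identity_at_full_depth():
    t = make_table([[6, 3, 1], [5, 5, 0]])
    out = rarefy(t, 10, seed=1)
    np.testing.assert_array_equal(out.counts, t.counts)


@given(
    counts=st.lists(
        st.lists(st.integers(0, 40), min_size=3, max_size=3), min_size=2, max_size=4
    ),
    depth=st.integers(1, 20),
)
@settings(max_examples=50, deadline=None)
def test_rarefy_conserves_depth_and_never_exceeds(counts, depth):
    counts = np.asarray(counts)
    if (counts.sum(axis=1) < depth).any():
        return
    t = make_table(counts)
    out = rarefy(t, depth, seed=0)
    assert (out.counts.sum(axis=1) == depth).all()
    assert (out.counts <= t.counts).all()


def test_rarefy_errors_name_the_sample():
    t = make_table([[50, 50], [1, 1]], sample_ids=["big", "tiny"])
    with pytest.raises(ValueError, match="tiny"):
        rarefy(t, 10)
    with pytest.warns(UserWarning, match="tiny"):
        out = rarefy(t, 10, on_small="drop")
    assert out.sample_ids == ["big"]


def test_rarefy_matches_hypergeometric_expectation():
    """Counts (6,3,1) subsampled to 5: per-ASV inclusion matches the
    multivariate hypergeometric mean within 3 sigma over many seeds."""
    t = make_table([[6, 3, 1]])
    n_draws = 10_000
    totals = np.zeros(3)
    for seed in range(n_draws):
        totals += rarefy(t, 5, seed=seed).counts[0]
    N, n = 10, 5
    k = np.array([6, 3, 1])
    expect = n * k / N
    var = n * (k / N) * (1 - k / N) * (N - n) / (N - 1)
    sigma_mean = np.sqrt(var / n_draws)
    np.testing.assert_array_less(np.abs(totals / n_draws - expect), 3 * sigma_mean + 1e-12)


# -- alpha diversity ----------------------------------------------------------

def test_shannon_even_community_both_bases():
    t = make_table([[10, 10, 10, 10]])
    assert alpha_diversity(t, "e")[0].shannon == pytest.approx(math.log(4))
    assert alpha_diversity(t, "2")[0].shannon == pytest.approx(2.0)


def test_shannon_direct_formula():
    t = make_table([[5, 3, 2]])
    p = np.array([5, 3, 2]) / 10
    expect = -(p * np.log(p)).sum()  # = 1.0297 to 4 decimals
    res = alpha_diversity(t, "e")[0]
    assert res.shannon == pytest.approx(expect, abs=1e-12)
    assert res.shannon == pytest.approx(1.0297, abs=5e-5)
    assert res.observed == 3


def test_shannon_single_asv_and_bound():
    t = make_table([[7, 0, 0]])
    res = alpha_diversity(t)[0]
    assert res.shannon == 0.0 and res.observed == 1
    rng = np.random.default_rng(2)
    t2 = make_table(rng.integers(0, 30, size=(5, 12)))
    for r in alpha_diversity(t2, "2"):
        assert 0 <= r.shannon <= math.log2(max(r.observed, 1)) + 1e-12


# -- beta diversity -----------------------------------------------------------

def test_beta_identical_and_disjoint():
    same = make_table([[3, 1, 2], [3, 1, 2]])
    for m in ("bray_curtis", "jaccard"):
        assert beta_diversity(same, m).data[0, 1] == pytest.approx(0.0)
    disjoint = make_table([[3, 1, 0, 0], [0, 0, 2, 9]])
    for m in ("bray_curtis", "jaccard"):
        assert beta_diversity(disjoint, m).data[0, 1] == pytest.approx(1.0)


def test_beta_hand_example():
    t = make_table([[10, 0, 5], [5, 5, 5]])
    assert beta_diversity(t, "bray_curtis").data[0, 1] == pytest.approx(10 / 30)
    assert beta_diversity(t, "jaccard").data[0, 1] == pytest.approx(1 - 2 / 3)


@given(scale=st.integers(2, 50))
@settings(max_examples=20, deadline=None)
def test_jaccard_presence_only(scale):
    a = np.array([[4, 0, 1, 7], [0, 3, 3, 1]])
    b = a.copy()
    b[0] *= scale
    d1 = beta_diversity(make_table(a), "jaccard").data[0, 1]
    d2 = beta_diversity(make_table(b), "jaccard").data[0, 1]
    assert d1 == pytest.approx(d2)


def test_beta_bounded():
    rng = np.random.default_rng(0)
    t = make_table(rng.integers(0, 100, size=(6, 20)))
    for m in ("bray_curtis", "jaccard"):
        d = beta_diversity(t, m).data
        assert (d >= 0).all() and (d <= 1).all()


# -- UPGMA --------------------------------------------------------------------

def test_upgma_two_samples():
    dm = DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]), ids=["a", "b"])
    dend = upgma(dm)
    assert dend.merge_heights == [1.5]
    for tip in dend.tree.tips():
        assert tip.length == pytest.approx(1.5)


def test_upgma_hand_agglomeration():
    dm = DistanceMatrix(
        np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float), ids=["s1", "s2", "s3"]
    )
    dend = upgma(dm)
    assert dend.merge_heights == [1.0, 4.0]
    # s3 hangs off the root at height 4
    (s3,) = [t for t in dend.tree.tips() if t.name == "s3"]
    assert s3.length == pytest.approx(4.0)


def test_upgma_label_permutation_invariance():
    rng = np.random.default_rng(8)
    n = 6
    m = rng.uniform(0.1, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    ids = [f"s{i}" for i in range(n)]
    dend1 = upgma(DistanceMatrix(m, ids=ids))
    perm = rng.permutation(n)
    dend2 = upgma(DistanceMatrix(m[np.ix_(perm, perm)], ids=[ids[i] for i in perm]))

    def coph(dend):
        tips = {t.name: t for t in dend.tree.tips()}
        return {
            (a, b): tips[a].distance(tips[b])
            for a, b in itertools.combinations(sorted(tips), 2)
        }

    c1, c2 = coph(dend1), coph(dend2)
    for key in c1:
        assert c1[key] == pytest.approx(c2[key], abs=1e-9)


def test_upgma_matches_scipy_average_linkage():
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(4)
    m = rng.uniform(0.1, 1.0, size=(7, 7))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    dend = upgma(DistanceMatrix(m, ids=[f"s{i}" for i in range(7)]))
    heights = sorted(h * 2 for h in dend.merge_heights)  # scipy reports full distances
    scipy_heights = sorted(average(squareform(m))[:, 2])
    np.testing.assert_allclose(heights, scipy_heights, atol=1e-9)


def test_upgma_rejects_nan():
    dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
    dm._data = np.array([[0, np.nan], [np.nan, 0]])  # skbio blocks NaN at construction
    with pytest.raises(ValueError, match="non-finite"):
        upgma(dm)


# -- transect geography -------------------------------------------------------

def test_geographic_distances_transect():
    pos = {f"S{i + 1}": 1.5 * i / 9 for i in range(10)}
    dm = geographic_distances(SampleMetadata(pos), [f"S{i + 1}" for i in range(10)])
    assert dm["S1", "S10"] == pytest.approx(1.5)
    assert dm["S1", "S2"] == pytest.approx(1.5 / 9)
    assert (np.diag(dm.data) == 0).all()


# -- Mantel -------------------------------------------------------------------

def _random_dm(n, rng, ids=None):
    m = rng.uniform(0.1, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(m, ids=ids or [f"s{i}" for i in range(n)])


def test_mantel_self_correlation():
    rng = np.random.default_rng(9)
    dm = _random_dm(10, rng)
    res = mantel(dm, dm, n_permutations=999, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 1000)
    assert not res.exhaustive


def test_mantel_exhaustive_matches_enumeration():
    """On 4 labels the test enumerates all 24 relabellings exactly."""
    rng = np.random.default_rng(10)
    a, b = _random_dm(4, rng), _random_dm(4, rng)
    res = mantel(a, b, n_permutations=999, seed=0)
    assert res.exhaustive and res.n_permutations == 24

    xa = a.data[np.triu_indices(4, 1)]
    r_obs = np.corrcoef(xa, b.data[np.triu_indices(4, 1)])[0, 1]
    count = 0
    for perm in itertools.permutations(range(4)):
        bp = b.data[np.ix_(perm, perm)]
        if np.corrcoef(xa, bp[np.triu_indices(4, 1)])[0, 1] >= r_obs - 1e-12:
            count += 1
    assert res.p == pytest.approx(count / 24)
    assert res.r == pytest.approx(r_obs)


def test_mantel_agrees_with_skbio():
    rng = np.random.default_rng(12)
    a, b = _random_dm(15, rng), _random_dm(15, rng)
    res = mantel(a, b, n_permutations=999, seed=3)
    r_ref, p_ref, _ = skbio_mantel(a, b, permutations=999, alternative="greater", seed=5)
    assert res.r == pytest.approx(r_ref, abs=1e-12)
    assert res.p == pytest.approx(p_ref, abs=0.06)  # two seeded permutation streams


def test_mantel_errors():
    rng = np.random.default_rng(13)
    a = _random_dm(5, rng)
    flat = DistanceMatrix(np.ones((5, 5)) - np.eye(5), ids=a.ids)
    with pytest.raises(ValueError, match="variance"):
        mantel(a, flat)
    b = _random_dm(5, rng, ids=["x0", "x1", "x2", "x3", "x4"])
    with pytest.raises(ValueError, match="labels"):
        mantel(a, b)
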