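"""Hellinger distances, PCoA and ANOSIM, cross-checked against
independent implementations (scikit-bio) and brute-force enumeration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.ordination import pcoa as skbio_pcoa

from occubiome.beta import anosim, hellinger_distance, pairwise_distances, pcoa
from occubiome.tables import CompositionTable


def _composition_table(arr, ids=None):
    arr = np.asarray(arr, dtype=float).T  # features x samples
    ids = ids or [f"s{i}" for i in range(arr.shape[1])]
    return CompositionTable(
        pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])], columns=ids)
    )


class TestHellinger:
    def test_identity(self):
        assert hellinger_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_maximum(self):
        assert hellinger_distance([1, 0], [0, 1]) == pytest.approx(math.sqrt(2))

    def test_hand_evaluated_value(self):
        # sqrt((sqrt(.5)-1)^2 + (sqrt(.5)-0)^2) = sqrt(2 - sqrt(2))
        expected = math.sqrt(2.0 - math.sqrt(2.0))
        assert hellinger_distance([0.5, 0.5], [1, 0]) == pytest.approx(expected, abs=1e-12)

    def test_halved_convention_scales_by_sqrt2(self):
        a, b = [0.2, 0.3, 0.5], [0.6, 0.1, 0.3]
        assert hellinger_distance(a, b) == pytest.approx(
            hellinger_distance(a, b, halved=True) * math.sqrt(2)
        )

    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=5000))
    def test_metric_axioms(self, m, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.dirichlet(np.ones(m), size=3)
        dab = hellinger_distance(a, b)
        assert dab == pytest.approx(hellinger_distance(b, a), abs=1e-9)
        assert hellinger_distance(a, a) <= 1e-9
        assert dab <= hellinger_distance(a, c) + hellinger_distance(c, b) + 1e-9
        assert dab <= math.sqrt(2) + 1e-9


class TestPairwiseDistances:
    def test_duplicated_sample_zero_distance(self):
        comp = _composition_table([[0.5, 0.5], [0.5, 0.5], [1.0, 0.0]])
        dm = pairwise_distances(comp)
        assert dm["s0", "s1"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scalar_function(self, rng):
        rows = rng.dirichlet(np.ones(5), size=4)
        comp = _composition_table(rows)
        dm = pairwise_distances(comp)
        for i, j in itertools.combinations(range(4), 2):
            assert dm[f"s{i}", f"s{j}"] == pytest.approx(
                hellinger_distance(rows[i], rows[j]), abs=1e-12
            )


class TestPcoa:
    def test_reconstructs_planted_plane(self, rng):
        points = rng.normal(size=(7, 2))
        d = squareform(pdist(points))
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(7)]), n_axes=2)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_collinear_points_single_axis(self):
        points = np.array([[0.0], [1.0], [2.0], [3.0]])
        d = squareform(pdist(points))
        with pytest.warns(UserWarning):
            res = pcoa(DistanceMatrix(d), n_axes=3)
        assert res.coordinates.shape[1] == 1
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_samples_coincide(self):
        comp = _composition_table([[0.5, 0.5], [0.5, 0.5], [0.9, 0.1], [0.2, 0.8]])
        res = pcoa(pairwise_distances(comp), n_axes=2)
        np.testing.assert_allclose(
            res.coordinates.loc["s0"], res.coordinates.loc["s1"], atol=1e-9
        )

    def test_hellinger_matrix_embeds_without_negative_eigenvalues(self, rng):
        comp = _composition_table(rng.dirichlet(np.ones(20), size=10))
        res = pcoa(pairwise_distances(comp))
        assert res.eigenvalues.min() >= -1e-9

    def test_agrees_with_skbio(self, rng):
        comp = _composition_table(rng.dirichlet(np.ones(15), size=8))
        dm = pairwise_distances(comp)
        ours = pcoa(dm, n_axes=3)
        theirs = skbio_pcoa(dm, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )


def _brute_force_anosim_p(d, n1):
    """Independent oracle: exact ANOSIM p over all two-group label
    assignments, computed from first principles."""
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    denom = n * (n - 1) / 4.0

    def r_of(members):
        grp = np.ones(n)
        grp[list(members)] = 0
        within = grp[iu[0]] == grp[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_of(range(n1))
    rs = [r_of(c) for c in itertools.combinations(range(n), n1)]
    return r_obs, sum(r >= r_obs - 1e-12 for r in rs) / len(rs)


class TestAnosim:
    def test_perfect_separation_r_one(self):
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.95, 0.85],
                [0.9, 0.95, 0.0, 0.12],
                [0.8, 0.85, 0.12, 0.0],
            ]
        )
        res = anosim(DistanceMatrix(d), ["a", "a", "b", "b"], seed=0)
        assert res.r == pytest.approx(1.0)

    @pytest.mark.parametrize("n1, n2", [(2, 2), (3, 3)])
    def test_exact_p_matches_enumeration(self, rng, n1, n2):
        n = n1 + n2
        d = squareform(pdist(rng.normal(size=(n, 3))))
        labels = ["a"] * n1 + ["b"] * n2
        res = anosim(DistanceMatrix(d), labels, seed=1)
        r_obs, p_exact = _brute_force_anosim_p(d, n1)
        assert res.method == "exact"
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)
        assert res.p_value > 0

    def test_r_agrees_with_skbio(self, rng):
        comp = _composition_table(rng.dirichlet(np.ones(12), size=10))
        dm = pairwise_distances(comp)
        labels = ["a"] * 5 + ["b"] * 5
        ours = anosim(dm, labels, n_permutations=99, seed=0)
        theirs = skbio_anosim(dm, grouping=list(labels), permutations=99)
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_conventions_give_identical_r_and_p(self, rng):
        comp = _composition_table(rng.dirichlet(np.ones(12), size=8))
        labels = ["a"] * 4 + ["b"] * 4
        res1 = anosim(pairwise_distances(comp), labels, seed=5)
        res2 = anosim(pairwise_distances(comp, halved=True), labels, seed=5)
        assert res1.r == pytest.approx(res2.r, abs=1e-12)
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-12)

    def test_permutation_p_never_zero(self, rng):
        d = squareform(pdist(rng.normal(size=(14, 2))))
        labels = ["a"] * 7 + ["b"] * 7
        res = anosim(DistanceMatrix(d), labels, n_permutations=99, seed=3, exact=False)
        assert 0 < res.p_value <= 1
        assert res.method == "permutation"

    def test_small_group_rejected(self):
        d = squareform(pdist(np.arange(3.0).reshape(-1, 1)))
        with pytest.raises(ValueError):
            anosim(DistanceMatrix(d), ["a", "b", "b"], seed=0)

    def test_seeded_reproducibility(self, rng):
        d = squareform(pdist(rng.normal(size=(12, 2))))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = anosim(DistanceMatrix(d), labels, seed=7, exact=False)
        r2 = anosim(DistanceMatrix(d), labels, seed=7, exact=False)
        assert r1 == r2
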