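"""Jensen-Shannon similarity and layer-enrichment tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.spatial.distance import jensenshannon as scipy_jsd

from vesswall import (
    jensen_shannon_divergence,
    js_distance,
    layer_t_test,
    permutation_layer_test,
    similarity,
    similarity_matrix,
)
from tests.conftest import random_density

# hand-derived: p=(1/2,1/2), q=(1,0); m=(3/4,1/4)
# KL(p||m) = .5*log2(2/3) + .5*log2(2)   = 0.2075187496...
# KL(q||m) = log2(4/3)                   = 0.4150374993...
HAND_JSD = 0.5 * (0.5 * np.log2(2 / 3) + 0.5 + np.log2(4 / 3))


class TestJensenShannon:
    def test_identity_and_disjoint_bounds(self):
        rng = np.random.default_rng(12)
        p = random_density(rng)
        assert jensen_shannon_divergence(p, p) == 0.0
        assert jensen_shannon_divergence([1, 0], [0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_hand_derived_value(self):
        jsd = jensen_shannon_divergence([0.5, 0.5], [1.0, 0.0])
        assert jsd == pytest.approx(HAND_JSD, abs=1e-12)
        assert jsd == pytest.approx(0.3113, abs=5e-5)
        assert js_distance([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.5579, abs=5e-5)

    def test_agrees_with_scipy_distance(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p, q = random_density(rng), random_density(rng)
            assert js_distance(p, q) == pytest.approx(scipy_jsd(p, q, base=2), abs=1e-12)

    def test_input_validation(self):
        ok = np.full(4, 0.25)
        with pytest.raises(ValueError, match="length mismatch"):
            jensen_shannon_divergence(ok, np.full(5, 0.2))
        with pytest.raises(ValueError, match="negative"):
            jensen_shannon_divergence([1.2, -0.2], [0.5, 0.5])
        with pytest.raises(ValueError, match="sums to"):
            jensen_shannon_divergence([0.5, 0.4], [0.5, 0.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = (random_density(rng) for _ in range(3))
        d_pq, d_qp = js_distance(p, q), js_distance(q, p)
        assert d_pq == d_qp  # symmetry, exact
        assert 0 <= d_pq <= 1
        assert js_distance(p, q) <= js_distance(p, r) + js_distance(r, q) + 1e-12


class TestSimilarity:
    def test_identical_distributions_report_cap(self):
        p = np.full(10, 0.1)
        assert similarity(p, p) == 1e6
        assert similarity(p, p, cap=100.0) == 100.0

    def test_disjoint_supports_give_unit_similarity(self):
        assert similarity([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_additive_variant(self):
        p, q = [1.0, 0.0], [0.0, 1.0]
        assert similarity(p, q, additive=True) == pytest.approx(0.0, abs=1e-12)
        assert similarity(p, p, additive=True) == pytest.approx(1.0)

    def test_strictly_decreasing_along_mixture_path(self):
        rng = np.random.default_rng(14)
        p, q = random_density(rng), random_density(rng)
        sims = []
        for w in np.linspace(0, 1, 11):
            mix = (1 - w) * p + w * q
            sims.append(similarity(p, mix / mix.sum()))
        assert all(a > b for a, b in zip(sims, sims[1:]))


class TestSimilarityMatrix:
    def test_pairwise_entries_match_elementwise_ops(self):
        rng = np.random.default_rng(15)
        dists = {m: random_density(rng) for m in ("A", "B", "C")}
        sm = similarity_matrix(dists, reference="A")
        for i, j in itertools.combinations(range(3), 2):
            mi, mj = sm.markers[i], sm.markers[j]
            assert sm.distance[i, j] == pytest.approx(js_distance(dists[mi], dists[mj]))
            assert sm.similarity[i, j] == pytest.approx(similarity(dists[mi], dists[mj]))
        assert np.allclose(sm.distance, sm.distance.T)
        assert np.allclose(np.diag(sm.distance), 0)

    def test_identical_markers_hit_cap(self):
        p = np.full(100, 0.01)
        sm = similarity_matrix({"X": p, "Y": p.copy()})
        assert sm.similarity[0, 1] == 1e6

    def test_reference_ranking_sorted(self):
        rng = np.random.default_rng(16)
        ref = random_density(rng)
        near = 0.9 * ref + 0.1 * random_density(rng)
        far = random_density(rng)
        sm = similarity_matrix(
            {"REF": ref, "NEAR": near / near.sum(), "FAR": far}, reference="REF"
        )
        tbl = sm.reference_ranking
        assert list(tbl["similarity"]) == sorted(tbl["similarity"], reverse=True)
        assert tbl.iloc[0]["marker"] == "NEAR"

    def test_errors(self):
        p = np.full(4, 0.25)
        with pytest.raises(ValueError, match="at least 2"):
            similarity_matrix({"A": p})
        with pytest.raises(KeyError, match="reference"):
            similarity_matrix({"A": p, "B": p}, reference="Z")
        with pytest.raises(ValueError, match="mismatched bin counts"):
            similarity_matrix({"A": p, "B": np.full(5, 0.2)})


class TestLayerTTest:
    def test_identical_constant_groups_p_half(self):
        res = layer_t_test([0.3] * 5, [0.3] * 5)
        assert res.p_value == 0.5

    def test_large_separation_limit(self):
        a = 0.9 + 1e-4 * np.arange(8)
        b = 0.1 + 1e-4 * np.arange(8)
        assert layer_t_test(a, b, "greater").p_value < 1e-6
        assert layer_t_test(a, b, "less").p_value > 1 - 1e-6

    def test_matches_textbook_welch_formula(self):
        a = np.array([0.40, 0.42, 0.38, 0.41, 0.39])
        b = np.array([0.35, 0.36, 0.34, 0.37, 0.33])
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p_ref = float(stats.t.sf(t_ref, df))
        res = layer_t_test(a, b, "greater")
        assert res.statistic == pytest.approx(t_ref, abs=1e-9)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)

    def test_group_size_validated(self):
        with pytest.raises(ValueError, match=">= 2"):
            layer_t_test([1.0], [0.0, 0.1])
        with pytest.raises(ValueError, match="alternative"):
            layer_t_test([0.1, 0.2], [0.1, 0.2], alternative="two-sided")


class TestPermutationTest:
    def test_all_equal_values_p_one(self):
        res = permutation_layer_test([0.5] * 4, [0.5] * 4, n_perm=500, seed=1)
        assert res.p_value == 1.0

    def test_complete_separation_small_p(self):
        a = [10.0, 11, 12, 13, 14, 15]
        b = [0.0, 1, 2, 3, 4, 5]
        res = permutation_layer_test(a, b, n_perm=10_000, seed=2)
        assert res.p_value <= 0.005

    def test_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(0.5, 0.1, 8), rng.normal(0.4, 0.1, 8)
        r1 = permutation_layer_test(a, b, n_perm=2000, seed=7)
        r2 = permutation_layer_test(a, b, n_perm=2000, seed=7)
        r3 = permutation_layer_test(a, b, n_perm=2000, seed=8)
        assert r1.p_value == r2.p_value
        mc_se = np.sqrt(r1.p_value * (1 - r1.p_value) / 2000)
        assert abs(r3.p_value - r1.p_value) < 5 * mc_se + 1e-3

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(18)
        a, b = rng.normal(0.55, 0.1, 6), rng.normal(0.45, 0.1, 6)
        pooled = np.concatenate([a, b])
        observed = a.mean() - b.mean()
        count = total = 0
        for idx in itertools.combinations(range(12), 6):
            mask = np.zeros(12, bool)
            mask[list(idx)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            count += stat >= observed
            total += 1
        exact = count / total
        res = permutation_layer_test(a, b, n_perm=10_000, seed=3)
        mc_se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(res.p_value - exact) <= 2 * mc_se + 2e-4

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_layer_test([0.1, 0.2], [0.3, 0.4], n_perm=50)
        with pytest.raises(ValueError, match=">= 2"):
            permutation_layer_test([0.1], [0.3, 0.4])
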