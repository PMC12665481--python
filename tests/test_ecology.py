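"""Community statistics: oracles, metric axioms and reference cross-checks."""

import io

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from basaltbiome.ecology import (AsvTable, DistanceMatrix, anova_lm, cut_tree,
                                 observed_richness, pcoa, permanova,
                                 permanova_terms, rarefy, spearman_matrix,
                                 spearman_rho, unifrac_unweighted, ward_hac)
from conftest import random_community_fixture


# ---------------------------------------------------------------- rarefaction

class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = AsvTable(np.array([[5, 5], [50, 50]]), ["a", "b"], ["x", "y"])
        out = rarefy(t, 10, seed=0)
        assert list(out.sample_ids) == ["a", "b"]
        np.testing.assert_array_equal(out.counts[0], [5, 5])

    def test_row_sums_equal_depth_and_shallow_samples_dropped(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(6, 30))
        counts[2] = 0          # empty sample must be dropped
        t = AsvTable(counts, [f"s{i}" for i in range(6)],
                     [f"a{j}" for j in range(30)])
        depth = 100
        out = rarefy(t, depth, seed=1)
        assert "s2" not in out.sample_ids
        assert (out.counts.sum(axis=1) == depth).all()
        assert (out.counts.sum(axis=0) > 0).all()

    def test_all_below_depth_errors(self):
        t = AsvTable(np.array([[1, 1]]), ["a"], ["x", "y"])
        with pytest.raises(ValueError, match="below rarefaction depth"):
            rarefy(t, 100, seed=0)

    def test_hypergeometric_expectation(self):
        # (990, 10) rarefied to 100: E[rare ASV] = 100*10/1000 = 1
        t = AsvTable(np.array([[990, 10]]), ["s"], ["common", "rare"])
        draws = []
        for seed in range(1000):
            out = rarefy(t, 100, seed=seed)
            d = dict(zip(out.asv_ids, out.counts[0]))
            draws.append(d.get("rare", 0))
        mean = np.mean(draws)
        # hypergeometric variance: n*p*(1-p)*(N-n)/(N-1)
        se = np.sqrt(100 * 0.01 * 0.99 * 900 / 999 / 1000)
        assert abs(mean - 1.0) < 3 * se


def test_observed_richness_identity():
    t = AsvTable(np.array([[0, 0, 0], [3, 1, 0]]), ["z", "k"], ["a", "b", "c"])
    r = observed_richness(t)
    assert r["z"] == 0 and r["k"] == 2


# ------------------------------------------------------------------- UniFrac

class TestUnifrac:
    def test_hand_worked_oracles(self, four_leaf_tree):
        t = AsvTable(np.array([[1, 0, 0, 0],
                               [0, 0, 1, 0],
                               [1, 1, 0, 0]]),
                     ["sA", "sC", "sAB"], ["A", "B", "C", "D"])
        D = unifrac_unweighted(t, four_leaf_tree)
        assert D.data[0, 1] == pytest.approx(1.0)        # {A} vs {C}
        assert D.data[0, 2] == pytest.approx(1 / 3)      # {A} vs {A,B}

    def test_identical_profiles_are_zero(self, four_leaf_tree):
        t = AsvTable(np.array([[1, 2, 0, 0], [5, 1, 0, 0]]),
                     ["x", "y"], ["A", "B", "C", "D"])
        D = unifrac_unweighted(t, four_leaf_tree)
        assert D.data[0, 1] == 0.0

    def test_presence_only_counts_are_irrelevant(self):
        table, tree = random_community_fixture(3)
        d1 = unifrac_unweighted(table, tree)
        doubled = AsvTable(table.counts * 2, table.sample_ids, table.asv_ids)
        d2 = unifrac_unweighted(doubled, tree)
        np.testing.assert_allclose(d1.data, d2.data)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_metric_axioms_on_random_fixtures(self, seed):
        table, tree = random_community_fixture(seed, n_samples=8, n_asvs=16)
        D = unifrac_unweighted(table, tree).data
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
        assert (D >= 0).all() and (D <= 1).all()
        n = D.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_missing_asv_in_tree_errors(self, four_leaf_tree):
        t = AsvTable(np.array([[1, 1]]), ["s"], ["A", "ZZZ"])
        with pytest.raises(ValueError, match="ZZZ"):
            unifrac_unweighted(t, four_leaf_tree)

    @pytest.mark.parametrize("seed", [10, 11, 12, 13, 14])
    def test_against_reference_implementation(self, seed):
        """Cross-check against scikit-bio on random fixtures."""
        skbio = pytest.importorskip("skbio")
        from skbio.diversity import beta_diversity

        table, tree = random_community_fixture(seed, n_samples=6, n_asvs=12)
        ours = unifrac_unweighted(table, tree)
        sk_tree = skbio.TreeNode.read(
            io.StringIO(tree.as_string(schema="newick").replace("'", "")),
            convert_underscores=False)
        ref = beta_diversity("unweighted_unifrac", table.counts,
                             ids=table.sample_ids, taxa=table.asv_ids,
                             tree=sk_tree)
        np.testing.assert_allclose(ours.data, ref.data, atol=1e-8)


# ---------------------------------------------------------------------- PCoA

class TestPcoa:
    def test_two_point_oracle(self):
        res = pcoa(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert res.eigenvalues[0] == pytest.approx(2.0)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        D = squareform(pdist(X))
        res = pcoa(D)
        D2 = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(D, D2, atol=1e-9)

    def test_eigenvalue_sum_is_trace(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        D = squareform(pdist(X))
        from basaltbiome.ecology import _gower_center
        res = pcoa(D)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(_gower_center(D)))

    def test_proportions_nonincreasing_and_sum_to_at_most_one(self):
        table, tree = random_community_fixture(7, n_samples=8, n_asvs=20)
        res = pcoa(unifrac_unweighted(table, tree))
        p = res.proportion_explained
        assert (np.diff(p) <= 1e-12).all()
        assert p.sum() <= 1 + 1e-9


# ---------------------------------------------------------------------- Ward

class TestWard:
    def test_two_points_single_merge(self):
        Z = ward_hac(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(3.0)

    def test_three_point_first_merge(self):
        D = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]])
        Z = ward_hac(D)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        # Lance-Williams: d(12,3)^2 = (2*100 + 2*100 - 1)/3
        assert Z[1, 2] == pytest.approx(np.sqrt(399 / 3))

    def test_matches_scipy_on_euclidean_data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        D = squareform(pdist(X))
        Z_ours = ward_hac(D)
        Z_ref = linkage(pdist(X), method="ward")
        np.testing.assert_allclose(sorted(Z_ours[:, 2]), sorted(Z_ref[:, 2]),
                                   atol=1e-8)
        ours = cut_tree(Z_ours, 3)
        ref = fcluster(Z_ref, t=3, criterion="maxclust")
        assert _same_partition(ours, ref)

    def test_recovers_well_separated_clusters(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.5, size=(6, 2))
        b = rng.normal(10, 0.5, size=(6, 2))
        D = squareform(pdist(np.vstack([a, b])))
        labels = cut_tree(ward_hac(D), 2)
        truth = np.array([0] * 6 + [1] * 6)
        assert _same_partition(labels, truth)


def _same_partition(a, b) -> bool:
    pairs_a = {(i, j) for i in range(len(a)) for j in range(i + 1, len(a))
               if a[i] == a[j]}
    pairs_b = {(i, j) for i in range(len(b)) for j in range(i + 1, len(b))
               if b[i] == b[j]}
    return pairs_a == pairs_b


# ----------------------------------------------------------------- PERMANOVA

class TestPermanova:
    def test_hand_worked_two_group_toy(self):
        D = np.array([[0, 1, 2, 2], [1, 0, 2, 2],
                      [2, 2, 0, 1], [2, 2, 1, 0]], float)
        res = permanova(D, {"g": ["a", "a", "b", "b"]}, n_perm=99, seed=0)
        assert res["SS_total"] == pytest.approx(4.5)
        assert res["R2"] == pytest.approx(3.5 / 4.5)
        assert res["pseudo_F"] == pytest.approx(7.0)

    def test_reorder_invariance(self):
        table, tree = random_community_fixture(21, n_samples=8, n_asvs=16)
        D = unifrac_unweighted(table, tree).data
        x = np.arange(8.0)
        r1 = permanova(D, {"x": x}, n_perm=0, seed=0)
        perm = np.random.default_rng(0).permutation(8)
        r2 = permanova(D[np.ix_(perm, perm)], {"x": x[perm]}, n_perm=0, seed=0)
        assert r1["R2"] == pytest.approx(r2["R2"], rel=1e-12)

    def test_seeded_reproducibility_and_seed_stability(self):
        table, tree = random_community_fixture(22, n_samples=10, n_asvs=20)
        D = unifrac_unweighted(table, tree)
        x = {"x": np.random.default_rng(1).normal(size=10)}
        p1 = permanova(D, x, n_perm=199, seed=7)["p"]
        p2 = permanova(D, x, n_perm=199, seed=7)["p"]
        assert p1 == p2
        ps = [permanova(D, x, n_perm=199, seed=s)["p"] for s in range(5)]
        assert max(ps) - min(ps) <= 10 * 2 / 200   # stable across seeds

    def test_constant_predictor_errors(self):
        D = np.array([[0, 1], [1, 0]], float)
        with pytest.raises(ValueError, match="no variance"):
            permanova(D, {"x": [1.0, 1.0]}, n_perm=9, seed=0)

    def test_type_one_error_calibrated(self):
        """Null p-values reject at ~alpha over simulated datasets."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            X = rng.normal(size=(15, 3))
            D = squareform(pdist(X))
            x = {"x": rng.normal(size=15)}
            p = permanova(D, x, n_perm=199, seed=int(rng.integers(2**31)))["p"]
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    @pytest.mark.parametrize("seed", [31, 32, 33, 34, 35])
    def test_pseudo_f_matches_reference_implementation(self, seed):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        table, tree = random_community_fixture(seed, n_samples=9, n_asvs=18)
        D = unifrac_unweighted(table, tree)
        grouping = ["g1"] * 4 + ["g2"] * 3 + ["g3"] * 2
        ours = permanova(D, {"g": grouping}, n_perm=99, seed=0)
        ref = sk_permanova(skbio.DistanceMatrix(D.data, D.ids),
                           grouping=grouping, permutations=99)
        assert ours["pseudo_F"] == pytest.approx(ref["test statistic"], abs=1e-8)
        # R2 implied by the reference F equals ours
        dfm, dfr = ours["df_model"], ours["df_resid"]
        r2_ref = ref["test statistic"] * dfm / (ref["test statistic"] * dfm + dfr)
        assert ours["R2"] == pytest.approx(r2_ref, abs=1e-8)

    def test_sequential_terms_sum_to_joint_model(self):
        table, tree = random_community_fixture(41, n_samples=12, n_asvs=24)
        D = unifrac_unweighted(table, tree)
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"a": rng.normal(size=12), "b": rng.normal(size=12)})
        tab = permanova_terms(D, X, n_perm=99, seed=0)
        joint = permanova(D, X, n_perm=0, seed=0)
        assert tab["SS"].sum() == pytest.approx(joint["SS_model"], rel=1e-9)


# ------------------------------------------------------- Spearman and ANOVA

class TestSpearman:
    def test_hand_worked_rho(self):
        assert spearman_rho(np.array([1, 2, 3.]),
                            np.array([3, 1, 2.])) == pytest.approx(-0.5)

    def test_rank_invariance_under_monotone_transform(self):
        x = np.array([0.1, 2.0, 3.5, 7.0, 9.9])
        assert spearman_rho(np.exp(x), x) == pytest.approx(1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        ref_r, ref_p = sps.spearmanr(x, y)
        df = pd.DataFrame({"x": x, "y": y})
        out = spearman_matrix(df)
        assert out["rho"].loc["x", "y"] == pytest.approx(ref_r, abs=1e-12)
        assert out["p"].loc["x", "y"] == pytest.approx(ref_p, abs=1e-10)

    def test_pairwise_complete_and_minimum_n(self):
        df = pd.DataFrame({
            "a": [1, 2, 3, 4, np.nan],
            "b": [2, 1, 4, np.nan, 5],
            "c": [1, np.nan, np.nan, np.nan, 2],
        })
        out = spearman_matrix(df)
        assert out["n"].loc["a", "b"] == 3
        assert np.isnan(out["rho"].loc["a", "c"])   # only 2 complete pairs


class TestAnova:
    def test_perfect_fit(self):
        res = anova_lm([2, 4, 6, 8.], [1, 2, 3, 4.])
        assert res["R2"] == 1.0 and res["p"] == 0.0

    def test_flat_slope_three_points(self):
        res = anova_lm([0, 1, 0.], [0, 1, 2.])
        assert res["F"] == pytest.approx(0.0)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(11)
        ps = [anova_lm(rng.normal(size=12), rng.normal(size=12))["p"]
              for _ in range(1000)]
        stat = sps.kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="no variance"):
            anova_lm([1, 2, 3.], [5, 5, 5.])
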