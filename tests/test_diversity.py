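"""Rarefaction, UniFrac, Bray-Curtis, PCoA and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import microsig as ms
from _oracles import unifrac_brute, unifrac_oracle_max_diff, permanova_brute_f


def table_of(rows, samples, taxa) -> ms.TaxonTable:
    return ms.TaxonTable(pd.DataFrame(rows, index=samples, columns=taxa))


class TestRarefy:
    def test_single_taxon_forced(self):
        table = table_of([[10, 0, 0]], ["s1"], ["a", "b", "c"])
        out = ms.rarefy(table, 5, seed=0)
        assert list(out.counts.loc["s1"]) == [5, 0, 0]

    def test_rows_sum_to_depth(self, cohort):
        _, table, _, _ = cohort
        out = ms.rarefy(table, 2000, seed=1)
        assert (out.library_sizes == 2000).all()

    def test_never_introduces_taxa(self, cohort):
        _, table, _, _ = cohort
        out = ms.rarefy(table, 2000, seed=2)
        zero_in = table.counts.loc[out.sample_ids].to_numpy() == 0
        assert (out.counts.to_numpy()[zero_in] == 0).all()

    def test_shallow_samples_dropped_with_warning(self):
        table = table_of([[10, 10], [2, 1]], ["deep", "shallow"], ["a", "b"])
        with pytest.warns(UserWarning, match="shallow"):
            out = ms.rarefy(table, 10, seed=0)
        assert out.sample_ids == ["deep"]

    def test_all_below_depth_errors(self):
        table = table_of([[1, 1]], ["s1"], ["a", "b"])
        with pytest.raises(ValueError, match="fewer"):
            ms.rarefy(table, 100, seed=0)

    def test_hypergeometric_moments(self):
        """Draws of (3,3) at depth 4 match exact hypergeometric moments."""
        table = table_of([[3, 3]], ["s1"], ["a", "b"])
        n_rep = 10_000
        draws = np.array([ms.rarefy(table, 4, seed=s).counts.iloc[0, 0]
                          for s in range(n_rep)])
        mean, var = 2.0, 4 * 0.5 * 0.5 * (6 - 4) / (6 - 1)  # = 0.4
        se_mean = np.sqrt(var / n_rep)
        assert abs(draws.mean() - mean) < 3 * se_mean
        # fourth-moment-based s.e. of the sample variance
        mu4 = np.mean((draws - draws.mean()) ** 4)
        se_var = np.sqrt((mu4 - var**2) / n_rep)
        assert abs(draws.var() - var) < 3 * se_var


class TestUnifrac:
    def test_identical_profiles_zero(self, four_leaf_tree):
        table = table_of([[1, 0, 2, 0], [5, 0, 9, 0]], ["s1", "s2"],
                         ["A", "B", "C", "D"])
        dm = ms.unweighted_unifrac(four_leaf_tree, table)
        assert dm["s1", "s2"] == 0.0

    def test_disjoint_clades_distance_one(self, four_leaf_tree):
        table = table_of([[1, 0, 0, 0], [0, 0, 1, 0]], ["s1", "s2"],
                         ["A", "B", "C", "D"])
        dm = ms.unweighted_unifrac(four_leaf_tree, table)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_nested_presence_one_third(self, four_leaf_tree):
        # s1={A,B}, s2={A}: unique edge B:1 over union {A:1,B:1,AB:1} = 1/3
        table = table_of([[1, 1, 0, 0], [1, 0, 0, 0]], ["s1", "s2"],
                         ["A", "B", "C", "D"])
        dm = ms.unweighted_unifrac(four_leaf_tree, table)
        assert dm["s1", "s2"] == pytest.approx(1.0 / 3.0)

    def test_missing_taxon_strict_error(self, four_leaf_tree):
        table = table_of([[1, 1]], ["s1"], ["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            ms.unweighted_unifrac(four_leaf_tree, table)

    def test_matches_brute_force_on_random_trees(self):
        assert unifrac_oracle_max_diff(50, seed=123) < 1e-12

    def test_matches_skbio(self):
        from skbio.diversity import beta_diversity
        tree = ms.simulate_tree(12, seed=4)
        rng = np.random.default_rng(5)
        taxa = [t.name for t in tree.tips()]
        counts = rng.integers(0, 3, size=(5, 12))
        counts[:, 0] += 1
        table = table_of(counts, [f"s{i}" for i in range(5)], taxa)
        ours = ms.unweighted_unifrac(tree, table)
        ref = beta_diversity("unweighted_unifrac", counts,
                             ids=table.sample_ids, tree=tree, taxa=taxa)
        np.testing.assert_allclose(ours.data, ref.data, atol=1e-12)

    def test_shared_taxon_never_increases_distance(self, four_leaf_tree):
        before = ms.unweighted_unifrac(
            four_leaf_tree,
            table_of([[1, 1, 0, 0], [1, 0, 1, 0]], ["s1", "s2"],
                     ["A", "B", "C", "D"]))["s1", "s2"]
        after = ms.unweighted_unifrac(
            four_leaf_tree,
            table_of([[1, 1, 0, 1], [1, 0, 1, 1]], ["s1", "s2"],
                     ["A", "B", "C", "D"]))["s1", "s2"]
        assert after <= before

    def test_bounds_and_symmetry(self, cohort):
        _, table, _, _ = cohort
        tree = ms.simulate_tree(60, seed=1)
        sub = ms.TaxonTable(table.counts.iloc[:6])
        dm = ms.unweighted_unifrac(tree, sub)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        np.testing.assert_allclose(dm.data, dm.data.T)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        rel = table_of([[2, 2], [4, 4]], ["s1", "s2"], ["a", "b"]).to_relative()
        assert ms.bray_curtis(rel)["s1", "s2"] == 0.0

    def test_disjoint_support_one(self):
        rel = table_of([[3, 0], [0, 7]], ["s1", "s2"], ["a", "b"]).to_relative()
        assert ms.bray_curtis(rel)["s1", "s2"] == pytest.approx(1.0)

    def test_hand_case(self):
        rel = table_of([[2, 2, 0], [1, 1, 2]], ["s1", "s2"],
                       ["a", "b", "c"]).to_relative()
        assert ms.bray_curtis(rel)["s1", "s2"] == pytest.approx(0.5)


class TestPcoa:
    def test_collinear_points(self):
        dm = DistanceMatrix([[0, 1, 3], [1, 0, 2], [3, 2, 0]],
                            ids=["a", "b", "c"])
        res = ms.pcoa(dm)
        positive = res.eigvals[res.eigvals > 1e-9]
        assert len(positive) == 1
        x = res.samples["PC1"]
        gaps = sorted([abs(x["a"] - x["b"]), abs(x["b"] - x["c"]),
                       abs(x["a"] - x["c"])])
        np.testing.assert_allclose(gaps, [1, 2, 3], atol=1e-9)

    def test_all_zero_matrix(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=["a", "b", "c"])
        res = ms.pcoa(dm)
        np.testing.assert_allclose(res.eigvals, 0.0, atol=1e-12)
        assert res.samples.shape[1] == 0

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(7, 3))
        dm = DistanceMatrix(squareform(pdist(points)),
                            ids=[f"s{i}" for i in range(7)])
        res = ms.pcoa(dm)
        rebuilt = squareform(pdist(res.samples.to_numpy()))
        np.testing.assert_allclose(rebuilt, dm.data, atol=1e-8)

    def test_proportions_valid(self):
        rng = np.random.default_rng(1)
        points = rng.normal(size=(6, 4))
        dm = DistanceMatrix(squareform(pdist(points)),
                            ids=[f"s{i}" for i in range(6)])
        res = ms.pcoa(dm)
        assert (res.proportion_explained >= 0).all()
        assert res.proportion_explained.sum() <= 1 + 1e-12
        assert (np.diff(res.eigvals) <= 1e-9).all()  # descending


class TestPermanova:
    def test_extreme_separation_min_p(self):
        """With zero within- and unit between-group distances, p reaches the
        design's floor: only permutations reproducing the split tie the
        observed statistic.  For 2+2 that happens with probability 1/3
        (8 of 24 label arrangements), so p concentrates near 1/3; for 6+6
        the probability is 2/C(12,6) and p is typically 1/(n_perm+1)."""
        def separated(n_per_group):
            n = 2 * n_per_group
            d = np.ones((n, n))
            d[:n_per_group, :n_per_group] = 0.0
            d[n_per_group:, n_per_group:] = 0.0
            np.fill_diagonal(d, 0.0)
            ids = [f"s{i}" for i in range(n)]
            groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                               index=ids)
            return DistanceMatrix(d, ids=ids), groups

        dm, groups = separated(2)
        res = ms.permanova(dm, groups, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=0.06)

        dm, groups = separated(6)
        res = ms.permanova(dm, groups, n_perm=99, seed=0)
        assert res.p_value <= 3.0 / 100.0

    def test_pseudo_f_matches_brute_force(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(4, 2))
        dm = DistanceMatrix(squareform(pdist(points)),
                            ids=["a1", "a2", "b1", "b2"])
        groups = pd.Series(["A", "A", "B", "B"],
                           index=["a1", "a2", "b1", "b2"])
        res = ms.permanova(dm, groups, n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(permanova_brute_f(dm, groups),
                                             rel=1e-12)

    def test_pseudo_f_matches_skbio(self):
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(4)
        points = rng.normal(size=(10, 3))
        ids = [f"s{i}" for i in range(10)]
        dm = DistanceMatrix(squareform(pdist(points)), ids=ids)
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=ids)
        ours = ms.permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio_permanova(dm, groups.to_numpy(), permutations=0)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_small_group_rejected(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=["a", "b", "c"])
        groups = pd.Series(["A", "A", "B"], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="2 samples"):
            ms.permanova(dm, groups, n_perm=99, seed=0)

    def test_p_never_zero(self):
        res_min = 1.0 / (99 + 1)
        d = np.ones((8, 8)) - np.eye(8)
        d[:4, :4] = 0; d[4:, 4:] = 0
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(d, ids=ids)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=ids)
        res = ms.permanova(dm, groups, n_perm=99, seed=1)
        assert res.p_value >= res_min
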