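"""Pearson distance, average-linkage trees, CAST, and profile optimization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cuprofile.clustering import (
    DistanceMatrix,
    ZeroVarianceWarning,
    cast_clusters,
    correlation_matrix,
    distance_matrix,
    double_optimization,
    hac_average_linkage,
    pair_correlation_report,
    pearson_correlation,
    raw_affinity,
    single_optimization,
)
from cuprofile.profiles import GenusProfile
from cuprofile.synthetic import phi_from_table, sample_copresence_pair

from oracles import naive_average_linkage


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == 1.0

    def test_sign_flip_gives_minus_one(self):
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_binary_example(self):
        # r = 0.5 / sqrt(0.75) from the closed form
        r = pearson_correlation([1, 0, 0, 1], [1, 0, 1, 1])
        assert r == pytest.approx(0.5 / np.sqrt(0.75))

    def test_zero_variance_gives_sentinel_with_warning(self):
        with pytest.warns(ZeroVarianceWarning):
            assert pearson_correlation([1, 1, 1], [1, 2, 3]) == 0.0

    def test_identical_constant_vectors_correlate_perfectly(self):
        # indistinguishable items must not be pushed apart by the sentinel
        assert pearson_correlation([0, 0, 0], [0, 0, 0]) == 1.0

    def test_length_mismatch_and_short_input_are_invalid(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_correlation([1], [2])


class TestDistanceMatrix:
    def test_duplicate_columns_have_zero_distance(self, toy_profile):
        prof = toy_profile
        prof.intervals["P1b"] = prof.intervals["P1"]
        prof.fractions["P1b"] = prof.fractions["P1"]
        d = distance_matrix(prof, axis="proteins")
        assert d.get("P1", "P1b") == pytest.approx(0.0)

    def test_anticorrelated_pair_has_distance_two(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1], "b": [1, 0, 1, 0]})
        d = distance_matrix(df, axis="proteins")
        assert d.get("a", "b") == pytest.approx(2.0)

    def test_matches_elementwise_correlation_oracle(self, toy_profile):
        d = distance_matrix(toy_profile, axis="proteins")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroVarianceWarning)
            corr = correlation_matrix(toy_profile.intervals)
        expect = 1.0 - corr.to_numpy()
        np.fill_diagonal(expect, 0.0)
        assert np.allclose(d.values, expect)

    def test_symmetry_and_range_are_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        with pytest.raises(ValueError):
            distance_matrix(pd.DataFrame({"a": [1, 0]}), axis="proteins")


class TestAverageLinkage:
    def test_three_item_merge_heights(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.8], [0.1, 0, 0.6], [0.8, 0.6, 0]], dtype=float),
        )
        dendro = hac_average_linkage(d)
        assert dendro.merges[0] == (("A",), ("B",), pytest.approx(0.1))
        a, b, h = dendro.merges[1]
        assert sorted([a, b]) == [("A", "B"), ("C",)]
        assert h == pytest.approx(0.7)  # mean of 0.8 and 0.6

    def test_identical_items_merge_first_at_zero(self):
        vals = np.array([[0, 0.0, 0.5], [0.0, 0, 0.5], [0.5, 0.5, 0]], dtype=float)
        dendro = hac_average_linkage(DistanceMatrix(["x", "y", "z"], vals))
        assert dendro.merges[0][2] == pytest.approx(0.0)

    def test_single_leaf_has_no_merges(self):
        dendro = hac_average_linkage(DistanceMatrix(["only"], np.zeros((1, 1))))
        assert dendro.merges == [] and dendro.leaf_order == ["only"]

    def test_matches_naive_oracle_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            labels = [f"L{i}" for i in range(n)]
            v = rng.uniform(0.0, 2.0, size=(n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0.0)
            got = hac_average_linkage(DistanceMatrix(labels, v)).merges
            expect = naive_average_linkage(labels, v)
            for (ga, gb, gh), (ea, eb, eh) in zip(got, expect):
                assert sorted([ga, gb]) == sorted([ea, eb])
                assert gh == pytest.approx(eh)

    def test_merge_heights_never_decrease(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 10))
            v = rng.uniform(0.0, 2.0, size=(n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0.0)
            hs = [
                h
                for _, _, h in hac_average_linkage(
                    DistanceMatrix([f"L{i}" for i in range(n)], v)
                ).merges
            ]
            assert all(a <= b + 1e-12 for a, b in zip(hs, hs[1:]))

    def test_heights_agree_with_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = int(rng.integers(4, 10))
            v = rng.uniform(0.1, 2.0, size=(n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0.0)
            ours = [
                h
                for _, _, h in hac_average_linkage(
                    DistanceMatrix([f"L{i}" for i in range(n)], v)
                ).merges
            ]
            theirs = linkage(squareform(v), method="average")[:, 2]
            assert np.allclose(sorted(ours), sorted(theirs))

    def test_newick_has_all_leaves(self):
        import dendropy

        v = np.array([[0, 0.4, 1.0], [0.4, 0, 0.8], [1.0, 0.8, 0]], dtype=float)
        dendro = hac_average_linkage(DistanceMatrix(["a", "b", "c"], v))
        tree = dendropy.Tree.get(data=dendro.newick, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["a", "b", "c"]


def _block_affinity(sizes, within, between, rng=None, jitter=0.0):
    labels = [f"b{k}i{i}" for k, n in enumerate(sizes) for i in range(n)]
    blocks = [k for k, n in enumerate(sizes) for _ in range(n)]
    n = len(labels)
    a = np.full((n, n), between)
    for i in range(n):
        for j in range(n):
            if blocks[i] == blocks[j]:
                a[i, j] = within
    if jitter and rng is not None:
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        a += (noise + noise.T) / 2
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=labels, columns=labels), blocks


class TestCast:
    def test_recovers_block_diagonal_partition(self, rng):
        aff, blocks = _block_affinity([4, 3, 5], within=0.9, between=0.1)
        cs = cast_clusters(aff, t=0.5)
        got = cs.assignment()
        labels = list(aff.columns)
        partition = {}
        for lab in labels:
            partition.setdefault(got[lab], set()).add(lab)
        expected = {}
        for lab, blk in zip(labels, blocks):
            expected.setdefault(blk, set()).add(lab)
        assert sorted(map(sorted, partition.values())) == sorted(
            map(sorted, expected.values())
        )

    def test_full_affinity_gives_single_cluster(self):
        aff = pd.DataFrame(np.ones((4, 4)), index=list("abcd"), columns=list("abcd"))
        cs = cast_clusters(aff, t=1.0)
        assert cs.clusters == [["a", "b", "c", "d"]]

    def test_empty_input_gives_empty_clusterset(self):
        cs = cast_clusters(pd.DataFrame(), t=0.5)
        assert cs.clusters == []

    def test_partition_and_mean_affinity_invariants(self, rng):
        aff, _ = _block_affinity([5, 4], within=0.85, between=0.15, rng=rng, jitter=0.05)
        cs = cast_clusters(aff, t=0.5)
        labels = sorted(aff.columns)
        assert sorted(cs.labels) == labels  # partition covers everything once
        for cluster in cs.clusters:
            for m in cluster:
                mean = np.mean([aff.loc[m, y] for y in cluster])
                assert mean >= cs.affinity_threshold - 1e-9

    def test_asymmetric_affinity_is_invalid(self):
        bad = pd.DataFrame([[1.0, 0.2], [0.6, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cast_clusters(bad, t=0.5)


TOY_TREE = "((G1,G2),(G3,(G4,(G5,G6))));"


class TestOptimization:
    def test_single_optimization_groups_planted_column_blocks(self, toy_profile):
        opt = single_optimization(toy_profile, TOY_TREE)
        order = opt.col_order
        pos = {c: order.index(c) for c in order}
        assert abs(pos["P1"] - pos["P2"]) == 1
        assert abs(pos["P3"] - pos["P4"]) == 1

    def test_single_optimization_rows_follow_the_tree(self, toy_profile):
        opt = single_optimization(toy_profile, TOY_TREE)
        assert opt.row_order == ["G1", "G2", "G3", "G4", "G5", "G6"]

    def test_input_row_order_is_irrelevant(self, toy_profile):
        shuffled = GenusProfile(
            fractions=toy_profile.fractions.iloc[::-1],
            intervals=toy_profile.intervals.iloc[::-1],
            genus_sizes=toy_profile.genus_sizes.iloc[::-1],
        )
        a = single_optimization(toy_profile, TOY_TREE)
        b = single_optimization(shuffled, TOY_TREE)
        assert a.row_order == b.row_order and a.col_order == b.col_order

    def test_missing_genus_in_tree_is_a_lookup_error(self, toy_profile):
        with pytest.raises(KeyError, match="G6"):
            single_optimization(toy_profile, "((G1,G2),(G3,(G4,G5)));")

    def test_double_optimization_preserves_protein_order(self, toy_profile):
        double = double_optimization(toy_profile)
        protein_only = hac_average_linkage(
            distance_matrix(toy_profile, axis="proteins")
        )
        assert double.col_order == list(protein_only.leaf_order)

    def test_identical_rows_form_a_single_clade(self):
        fr = pd.DataFrame(
            {"P1": [1.0, 1.0, 1.0], "P2": [0.5, 0.5, 0.5], "P3": [0.0, 0.0, 0.0]},
            index=["Ga", "Gb", "Gc"],
        )
        prof = GenusProfile(
            fractions=fr,
            intervals=fr.map(lambda f: 0 if f == 0 else 10 if f == 1 else 5).astype(int),
            genus_sizes=pd.Series([2, 2, 2], index=fr.index),
        )
        opt = double_optimization(prof)
        assert opt.taxa_clusters.clusters == [["Ga", "Gb", "Gc"]]

    def test_all_zero_rows_cluster_together(self, toy_profile):
        fr = toy_profile.fractions.copy()
        iv = toy_profile.intervals.copy()
        for g in ("Z1", "Z2"):  # endosymbiont-like genera lacking every seed
            fr.loc[g] = 0.0
            iv.loc[g] = 0
        prof = GenusProfile(
            fractions=fr,
            intervals=iv.astype(int),
            genus_sizes=pd.Series([4] * 8, index=fr.index),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroVarianceWarning)
            opt = double_optimization(prof)
        assign = opt.clade_assignment()
        assert assign["Z1"] == assign["Z2"]
        assert {g for g, c in assign.items() if c == assign["Z1"]} == {"Z1", "Z2"}

    def test_degenerate_axes_are_invalid(self, toy_profile):
        single_col = GenusProfile(
            fractions=toy_profile.fractions[["P1"]],
            intervals=toy_profile.intervals[["P1"]],
            genus_sizes=toy_profile.genus_sizes,
        )
        with pytest.raises(ValueError):
            double_optimization(single_col)


class TestPairCorrelationReport:
    def test_identical_columns_are_confident(self):
        mat = pd.DataFrame({"A": [1, 0, 1, 0, 1], "B": [1, 0, 1, 0, 1]})
        rep = pair_correlation_report(mat)
        row = rep.iloc[0]
        assert row["r"] == pytest.approx(1.0) and bool(row["confident"])

    def test_independent_columns_have_small_r(self, rng):
        hits = 0
        trials = 40
        for _ in range(trials):
            mat = pd.DataFrame(rng.integers(0, 2, size=(200, 2)), columns=["A", "B"])
            r = pair_correlation_report(mat)["r"].iloc[0]
            if abs(r) < 0.3:
                hits += 1
        assert hits >= int(0.95 * trials)

    def test_planted_copresence_matches_phi_closed_form(self):
        table = (0.45, 0.05, 0.05, 0.45)
        expect = phi_from_table(*table)
        mat = sample_copresence_pair(*table, n_genomes=500, seed=13)
        r = pair_correlation_report(mat)["r"].iloc[0]
        assert expect == pytest.approx(0.8)
        assert abs(r - expect) < 0.05

    def test_affinity_flag_uses_raw_correlation(self):
        mat = pd.DataFrame({"A": [1, 1, 0, 0, 1], "B": [1, 1, 0, 1, 1]})
        rep = pair_correlation_report(mat)
        r = rep["r"].iloc[0]
        assert bool(rep["high_affinity"].iloc[0]) == (r >= 0.5)

    def test_raw_affinity_has_unit_diagonal(self):
        corr = pd.DataFrame(
            [[0.2, 0.6], [0.6, -0.1]], index=["a", "b"], columns=["a", "b"]
        )
        aff = raw_affinity(corr)
        assert np.allclose(np.diag(aff.to_numpy()), 1.0)
        assert aff.loc["a", "b"] == 0.6
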