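import numpy as np
import pandas as pd
import pytest

from ovitrace import newick_extra as ne


class TestParse:
    def test_two_leaf_tree(self):
        t = ne.parse_newick("(A,B);")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["A", "B"]

    def test_four_leaves_three_internal(self):
        t = ne.parse_newick("((A,B),(C,D));")
        leaves = list(t.leaf_node_iter())
        internal = [n for n in t.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 4 and len(internal) == 3

    def test_malformed_rejected(self):
        with pytest.raises(ne.NewickError):
            ne.parse_newick("((A,B);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ne.NewickError):
            ne.parse_newick("(A,(A,B));")

    def test_roundtrip_random_trees(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            labels = [f"L{i}" for i in range(rng.integers(3, 12))]
            # random binary tree by sequential attachment
            newick = _random_newick(labels, rng)
            t1 = ne.parse_newick(newick)
            t2 = ne.parse_newick(ne.write_newick(t1))
            assert _topology_key(t1) == _topology_key(t2)


def _random_newick(labels, rng):
    parts = list(labels)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return parts[0] + ";"


def _topology_key(tree):
    def key(node):
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sorted(key(c) for c in node.child_nodes())) + ")"

    return key(tree.seed_node)


class TestLevel1Neighbors:
    def test_cherry_sister(self):
        t = ne.parse_newick("((A,B),(C,D));")
        assert ne.level1_neighbors(t, "A") == {"B"}

    def test_asymmetric_ladder(self):
        t = ne.parse_newick("((M1,I1),(M2,(M3,I2)));")
        assert ne.level1_neighbors(t, "M2") == {"M3", "I2"}
        assert ne.level1_neighbors(t, "M3") == {"I2"}

    def test_polytomy_all_comembers(self):
        t = ne.parse_newick("(A,B,C);")
        assert ne.level1_neighbors(t, "A") == {"B", "C"}

    def test_missing_leaf_rejected(self):
        t = ne.parse_newick("(A,B);")
        with pytest.raises(ne.NewickError):
            ne.level1_neighbors(t, "Z")


class TestAffinityMatrix:
    def test_monophyletic_breeds_pure_rows(self):
        t = ne.parse_newick("((A1,A2),(B1,B2));")
        breeds = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        M = ne.affinity_matrix(t, breeds, percent=True)
        assert M.loc["A", "A"] == pytest.approx(100.0)
        assert M.loc["B", "B"] == pytest.approx(100.0)

    def test_hand_counted_ladder(self):
        t = ne.parse_newick("((M1,I1),(M2,(M3,I2)));")
        breeds = {"M1": "X", "M2": "X", "M3": "X", "I1": "Y", "I2": "Y"}
        M = ne.affinity_matrix(t, breeds, percent=True)
        assert M.loc["X", "X"] == pytest.approx(25.0)
        assert M.loc["X", "Y"] == pytest.approx(75.0)
        assert M.loc["Y", "X"] == pytest.approx(100.0)

    def test_counts_partition_neighbor_totals(self):
        t = ne.parse_newick("((M1,I1),(M2,(M3,I2)));")
        breeds = {"M1": "X", "M2": "X", "M3": "X", "I1": "Y", "I2": "Y"}
        M = ne.affinity_matrix(t, breeds)
        total = sum(
            len(ne.level1_neighbors(t, lf))
            for lf in ("M1", "M2", "M3", "I1", "I2")
        )
        assert M.values.sum() == total

    def test_unlabeled_leaf_rejected(self):
        t = ne.parse_newick("(A,B);")
        with pytest.raises(ne.NewickError):
            ne.affinity_matrix(t, {"A": "x"})


class TestAggregateRegions:
    BREEDS = {"M1": "X", "M2": "X", "M3": "X", "I1": "Y", "I2": "Y"}

    def test_single_region_identity(self):
        t = ne.parse_newick("((M1,I1),(M2,(M3,I2)));")
        M = ne.affinity_matrix(t, self.BREEDS)
        agg = ne.aggregate_regions(M, {"X": "rx", "Y": "ry"})
        assert np.allclose(agg.values, M.values)  # one breed per region

    def test_column_addition(self):
        counts = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["f"], columns=list("abcd"))
        agg = ne.aggregate_regions(
            counts, {"a": "r1", "b": "r1", "c": "r2", "d": "r2"})
        assert agg.loc["f", "r1"] == 3.0 and agg.loc["f", "r2"] == 7.0

    def test_percent_rows_sum_to_100_and_commute(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(1, 10, (3, 4)).astype(float),
                              index=list("fgh"), columns=list("abcd"))
        rmap = {"a": "r1", "b": "r1", "c": "r2", "d": "r2"}
        p1 = ne.aggregate_regions(counts, rmap, percent=True)
        p2 = ne.aggregate_regions(ne.to_percent(counts), rmap)
        assert np.allclose(p1.sum(axis=1), 100.0)
        assert np.allclose(p1.values, p2.values)

    def test_unmapped_breed_rejected(self):
        counts = pd.DataFrame([[1.0]], index=["f"], columns=["a"])
        with pytest.raises(ValueError):
            ne.aggregate_regions(counts, {})


class TestMatrixConcordance:
    def test_identical_matrices_r_one(self):
        m = np.arange(12.0).reshape(3, 4)
        r, p, N = ne.matrix_concordance(m, m)
        assert r == pytest.approx(1.0) and N == 12

    def test_affine_transform_r_one(self):
        m = np.arange(12.0).reshape(3, 4)
        r, _, _ = ne.matrix_concordance(m, 3.0 * m + 7.0)
        assert r == pytest.approx(1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(9)
        m1 = rng.random((6, 4))
        m2 = rng.random((6, 4))
        r, p, N = ne.matrix_concordance(m1, m2)
        x, y = m1.ravel(), m2.ravel()
        rr = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(rr, abs=1e-12)
        assert N == 24

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ne.matrix_concordance(np.ones((2, 2)), np.arange(4.0).reshape(2, 2))


class TestNJTree:
    def test_three_taxa_unique_topology(self):
        D = pd.DataFrame(
            [[0, 2, 3], [2, 0, 3], [3, 3, 0]],
            index=list("abc"), columns=list("abc"), dtype=float)
        t = ne.nj_tree(D)
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == list("abc")

    def test_recovers_additive_topology(self):
        """Distances generated from a known 5-taxon tree are additive, so
        neighbor joining must recover the generating topology."""
        # tree: ((a:1,b:2):1,(c:1,d:1):2,e:4)
        paths = {
            ("a", "b"): 3, ("a", "c"): 4, ("a", "d"): 4, ("a", "e"): 6,
            ("b", "c"): 5, ("b", "d"): 5, ("b", "e"): 7,
            ("c", "d"): 2, ("c", "e"): 7, ("d", "e"): 7,
        }
        ids = list("abcde")
        D = pd.DataFrame(0.0, index=ids, columns=ids)
        for (x, y), d in paths.items():
            D.loc[x, y] = D.loc[y, x] = d
        t = ne.nj_tree(D)
        # a,b form a clade on the unrooted tree: their path stays disjoint
        # from c,d's -> check split {a,b} | {c,d,e} exists via neighbors
        assert ne.level1_neighbors(t, "c") == {"d"} or \
            ne.level1_neighbors(t, "d") == {"c"}
        assert ne.level1_neighbors(t, "a") == {"b"} or \
            ne.level1_neighbors(t, "b") == {"a"}

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.random((6, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(6)]
        df = pd.DataFrame(D, index=ids, columns=ids)
        t1, t2 = ne.nj_tree(df), ne.nj_tree(df.iloc[::-1, ::-1])
        assert _topology_key_unrooted(t1) == _topology_key_unrooted(t2)

    def test_asymmetric_rejected(self):
        D = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"],
                         columns=["a", "b"], dtype=float)
        with pytest.raises(ValueError):
            ne.nj_tree(D)


def _topology_key_unrooted(tree):
    t = tree.clone(depth=1)
    t.encode_bipartitions()
    return frozenset(
        b.leafset_as_bitstring() for b in t.bipartition_encoding
    )
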