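"""Distances, UPGMA, bipartitions, bootstrap support and Newick round-trips."""

import numpy as np
import pytest

from oudphylo.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    cophenetic_matrix,
    distance_matrix,
    euclidean_distance,
    read_newick,
    reroot,
    rf_distance,
    upgma,
    write_newick,
)
from oudphylo.signature import OUDSignature
from oudphylo.simulate import random_ultrametric_tree


def sig(values, k=4, strain=""):
    v = np.zeros(4 ** k)
    v[: len(values)] = values
    return OUDSignature(k=k, values=v, strain=strain)


def dm_from(labels, entries):
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), v in entries.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(labels=list(labels), values=d)


class TestEuclideanDistance:
    def test_identity(self):
        x = sig([1.0, 2.0])
        assert euclidean_distance(x, x) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance(sig([0.0, 0.0]), sig([3.0, 4.0])) == 5.0

    def test_matches_componentwise_sum(self):
        rng = np.random.default_rng(0)
        x = OUDSignature(k=4, values=rng.normal(size=256))
        y = OUDSignature(k=4, values=rng.normal(size=256))
        brute = sum((a - b) ** 2 for a, b in zip(x.values, y.values)) ** 0.5
        assert euclidean_distance(x, y) == pytest.approx(brute, abs=1e-12)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance(sig([1.0], k=4), sig([1.0], k=6))


class TestDistanceMatrix:
    def test_identical_signatures_zero(self):
        dm = distance_matrix([sig([1, 2], strain="a"), sig([1, 2], strain="b")])
        assert dm.values[0, 1] == 0.0

    def test_duplicate_leaf_consistency(self):
        s1, s2 = sig([1, 0], strain="a"), sig([0, 1], strain="b")
        s3 = OUDSignature(k=4, values=s1.values.copy(), strain="c")
        dm = distance_matrix([s1, s2, s3])
        assert dm[("a", "c")] == 0.0
        assert dm[("a", "b")] == dm[("c", "b")]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix([sig([1], strain="a"), sig([2], strain="a")])

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        sigs = [
            OUDSignature(k=4, values=rng.normal(size=256), strain=f"s{i}")
            for i in range(6)
        ]
        dm = distance_matrix(sigs)
        np.testing.assert_array_equal(dm.values, dm.values.T)
        np.testing.assert_array_equal(np.diag(dm.values), np.zeros(6))


class TestUpgma:
    def test_three_taxon_hand_example(self):
        # d(A,B)=2, d(A,C)=d(B,C)=8 -> ((A,B),C), AB node at 1, root at 4
        dm = dm_from("ABC", {("A", "B"): 2, ("A", "C"): 8, ("B", "C"): 8})
        t = upgma(dm)
        assert bipartitions(t) == set()  # 3 leaves: no non-trivial split
        depths = t.leaf_depths()
        assert depths["A"] == depths["B"] == depths["C"] == pytest.approx(4.0)
        coph = cophenetic_matrix(t)
        assert coph[("A", "B")] == pytest.approx(2.0)
        assert coph[("A", "C")] == pytest.approx(8.0)

    def test_two_taxon_root_height(self):
        t = upgma(dm_from("AB", {("A", "B"): 6}))
        assert t.leaf_depths() == pytest.approx({"A": 3.0, "B": 3.0})
        assert write_newick(t).strip() in ("(A:3.0,B:3.0);", "(A:3,B:3);")

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_ultrametric_tree(self, seed):
        """UPGMA on cophenetic distances returns the generating tree."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 17))
        true = random_ultrametric_tree(n, depth=1.0, seed=seed)
        rebuilt = upgma(cophenetic_matrix(true))
        assert rf_distance(rebuilt, true) == 0
        d1, d2 = rebuilt.leaf_depths(), true.leaf_depths()
        for label in d1:
            assert abs(d1[label] - d2[label]) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_average_linkage(self, seed):
        """Cross-check cophenetic structure against scipy's average linkage."""
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(7, 30))
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        d = (d + d.T) / 2
        labels = [f"L{i}" for i in range(7)]
        t = upgma(DistanceMatrix(labels=labels, values=d))
        ours = cophenetic_matrix(t)
        ref = squareform(cophenet(average(squareform(d))))
        idx = [ours.labels.index(l) for l in labels]
        np.testing.assert_allclose(ours.values[np.ix_(idx, idx)], ref, atol=1e-9)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 20))
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        t = upgma(DistanceMatrix(labels=[f"L{i}" for i in range(9)], values=(d + d.T) / 2))
        assert t.is_ultrametric(tol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, np.inf], [np.inf, 0]]))


class TestBipartitions:
    def test_balanced_quartet(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert bipartitions(t) == {frozenset({"A", "B"})}

    def test_caterpillar(self):
        t = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        assert bipartitions(t) == {frozenset({"A", "B"})}

    def test_two_leaves_empty(self):
        assert bipartitions(read_newick("(A:1,B:1);")) == set()

    def test_five_leaf_counts(self):
        t = read_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        # canonical blocks: {A,B} and the smaller side {D,E} of {A,B,C}|{D,E}
        assert bipartitions(t) == {
            frozenset({"A", "B"}),
            frozenset({"D", "E"}),
        }


class TestRfDistance:
    def test_identical_trees(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(t1, t2) == 2
        assert rf_distance(t2, t1) == 2

    def test_label_mismatch_rejected(self):
        t1 = read_newick("(A:1,B:1);")
        t2 = read_newick("(A:1,C:1);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    def test_triangle_inequality_spot_check(self):
        trees = [
            read_newick(s)
            for s in (
                "(((A:1,B:1):1,C:2):1,(D:1,E:1):2);",
                "(((A:1,C:1):1,B:2):1,(D:1,E:1):2);",
                "((((A:1,B:1):1,D:2):1,C:3):1,E:4);",
            )
        ]
        for a in trees:
            for b in trees:
                for c in trees:
                    assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


class TestReroot:
    def test_bipartitions_invariant_for_every_leaf(self):
        t = upgma(cophenetic_matrix(random_ultrametric_tree(8, 1.0, seed=5)))
        ref = bipartitions(t)
        for leaf in sorted(t.leaf_labels):
            assert bipartitions(reroot(t, leaf)) == ref

    def test_idempotent(self):
        t = upgma(cophenetic_matrix(random_ultrametric_tree(6, 1.0, seed=6)))
        once = reroot(t, "T03")
        twice = reroot(once, "T03")
        assert write_newick(once) == write_newick(twice)

    def test_unknown_label_rejected(self):
        t = read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            reroot(t, "Z")


class TestBootstrap:
    @staticmethod
    def planted_signatures(offset=10.0, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=256)
        vals = {
            "s1": base + rng.normal(scale=noise, size=256),
            "s2": base + rng.normal(scale=noise, size=256),
            "s3": base + offset + rng.normal(scale=noise, size=256),
            "s4": base + offset + rng.normal(scale=noise, size=256),
        }
        return [OUDSignature(k=4, values=v, strain=s) for s, v in vals.items()]

    def test_planted_split_full_support(self):
        t = bootstrap_support(self.planted_signatures(), n_reps=50, seed=1)
        assert t.supports[frozenset({"s1", "s2"})] == 100.0

    def test_single_replicate_support_in_0_100(self):
        t = bootstrap_support(self.planted_signatures(), n_reps=1, seed=2)
        assert set(t.supports.values()) <= {0.0, 100.0}

    def test_only_internal_splits_scored(self):
        t = bootstrap_support(self.planted_signatures(), n_reps=5, seed=3)
        for split in t.supports:
            assert len(split) == 2  # 4 taxa: only one non-trivial split shape

    def test_reproducible(self):
        a = bootstrap_support(self.planted_signatures(), n_reps=30, seed=7)
        b = bootstrap_support(self.planted_signatures(), n_reps=30, seed=7)
        assert a.supports == b.supports
        assert write_newick(a) == write_newick(b)

    def test_support_concentrates_with_effect_size(self):
        """Planted-split support is non-decreasing in the offset magnitude."""
        mins = []
        for offset in (0.0, 0.3, 3.0):
            supports = []
            for seed in range(5):
                sigs = self.planted_signatures(offset=offset, noise=0.5, seed=seed)
                t = bootstrap_support(sigs, n_reps=40, seed=seed)
                supports.append(t.supports.get(frozenset({"s1", "s2"}), 0.0))
            mins.append(np.mean(supports))
        assert mins[0] <= mins[1] + 10 and mins[1] <= mins[2]
        assert mins[2] == 100.0

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.planted_signatures(), n_reps=0, seed=0)


class TestNewickIO:
    def test_round_trip_preserves_everything(self, tmp_path):
        sigs = TestBootstrap.planted_signatures()
        t = bootstrap_support(sigs, n_reps=20, seed=4)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert back.leaf_labels == t.leaf_labels
        assert bipartitions(back) == bipartitions(t)
        assert back.supports == t.supports
        d1, d2 = t.leaf_depths(), back.leaf_depths()
        for label in d1:
            assert abs(d1[label] - d2[label]) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_random_trees(self, tmp_path, seed):
        t = random_ultrametric_tree(int(5 + seed), depth=2.0, seed=seed)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert rf_distance(back, t) == 0
        d1, d2 = t.leaf_depths(), back.leaf_depths()
        for label in d1:
            assert abs(d1[label] - d2[label]) < 1e-9

    def test_unlabeled_internal_nodes_ok(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert t.supports == {}

    def test_malformed_newick_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1;")
        with pytest.raises(ValueError, match="malformed"):
            read_newick(p)
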