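import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from its2delimit.core import DistanceMatrix
from its2delimit.synthetic import simulate_coalescent_tree
from its2delimit.trees import (
    bootstrap_support,
    cophenetic_matrix,
    dendrogram_clades,
    from_newick,
    make_ultrametric,
    neighbor_joining,
    node_heights,
    prune_taxa,
    root_on_outgroup,
    single_linkage_tree,
    to_newick,
    tree_distance_matrix,
)


def random_additive_matrix(rng, n):
    """Path-length matrix of a random tree with positive edge lengths."""
    labels = [f"t{i}" for i in range(n)]
    tree, _ = simulate_coalescent_tree(labels, rng)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(e.length * rng.uniform(0.5, 2.0) + rng.uniform(0.05, 0.3))
    return tree_distance_matrix(tree)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        d = DistanceMatrix(["a", "b"], [[0, 0.6], [0.6, 0]])
        t = neighbor_joining(d)
        total = sum(e.length for e in t.preorder_edge_iter() if e.length)
        assert total == pytest.approx(0.6)

    def test_exact_recovery_of_additive_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            d = random_additive_matrix(rng, n)
            rec = tree_distance_matrix(neighbor_joining(d)).reorder(d.labels)
            assert np.allclose(rec.values, d.values, atol=1e-8)

    def test_label_permutation_equivariance(self, rng):
        d = random_additive_matrix(rng, 8)
        perm = list(rng.permutation(d.labels))
        t1 = tree_distance_matrix(neighbor_joining(d))
        t2 = tree_distance_matrix(neighbor_joining(d.reorder(perm)))
        assert np.allclose(t1.values, t2.reorder(t1.labels).values, atol=1e-8)

    def test_agrees_with_independent_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        d = random_additive_matrix(rng, 9)
        ours = tree_distance_matrix(neighbor_joining(d))
        sk_tree = skbio.tree.nj(
            skbio.DistanceMatrix(d.values, ids=d.labels)
        )
        n = len(d.labels)
        sk_vals = np.zeros((n, n))
        for i, a in enumerate(d.labels):
            for j, b in enumerate(d.labels):
                if i < j:
                    sk_vals[i, j] = sk_vals[j, i] = sk_tree.find(a).distance(
                        sk_tree.find(b)
                    )
        assert np.allclose(ours.reorder(d.labels).values, sk_vals, atol=1e-6)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a"], [[0.0]]))


class TestSingleLinkage:
    def test_three_four_five_merge_height(self):
        # rows (0,0) and (3,4) as features: Euclidean distance 5
        d = DistanceMatrix(["a", "b"], [[0.0, 0.0], [3.0, 4.0]], _validate=False)
        t = single_linkage_tree(d)
        assert t.seed_node.height == pytest.approx(5.0)

    def test_hand_single_linkage(self):
        vals = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        t = single_linkage_tree(DistanceMatrix(list("ABC"), vals))
        # (A,B) merges first: their feature rows are closest
        clades = {frozenset(c) for c in dendrogram_clades(t)}
        assert frozenset({"A", "B"}) in clades

    def test_cophenetic_matches_scipy_and_is_ultrametric(self, rng):
        pts = rng.normal(size=(8, 4))
        vals = squareform(pdist(pts))
        d = DistanceMatrix([f"t{i}" for i in range(8)], vals)
        t = single_linkage_tree(d, minkowski_p=2)
        coph = cophenetic_matrix(t)
        Z = linkage(pdist(d.values, metric="minkowski", p=2), method="single")
        expected = squareform(cophenet(Z))
        got = coph.reorder(d.labels).values
        assert np.allclose(got, expected, atol=1e-10)
        # ultrametric three-point condition
        n = len(d.labels)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert got[i, j] <= max(got[i, k], got[k, j]) + 1e-9

    def test_invalid_exponent(self):
        d = DistanceMatrix(list("ab"), [[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="Minkowski"):
            single_linkage_tree(d, minkowski_p=0.5)


class TestBootstrap:
    def test_duplicated_identical_blocks_give_full_support(self):
        block = np.array([[0.0, 0.1, 5.0], [0.1, 0.0, 5.0], [5.0, 5.0, 0.0]])
        features = np.hstack([block] * 6)
        t = bootstrap_support(features, list("abc"), n_boot=50, seed=3)
        supports = [n.support for n in t.preorder_node_iter()
                    if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_bit_stable(self, rng):
        features = rng.normal(size=(6, 10))
        labels = [f"t{i}" for i in range(6)]
        t1 = bootstrap_support(features, labels, n_boot=40, seed=9)
        t2 = bootstrap_support(features, labels, n_boot=40, seed=9)
        s1 = {c: n.support for c, n in dendrogram_clades(t1).items()}
        s2 = {c: n.support for c, n in dendrogram_clades(t2).items()}
        assert s1 == s2

    def test_unstable_taxon_has_minimal_support(self, rng):
        # two tight clusters plus one taxon whose features straddle them
        a = np.tile([0.0, 0.0, 0.0, 0.0], (3, 1)) + rng.normal(0, 0.01, (3, 4))
        b = np.tile([10.0, 10.0, 10.0, 10.0], (3, 1)) + rng.normal(0, 0.01, (3, 4))
        waverer = np.array([[0.0, 10.0, 0.0, 10.0]])
        features = np.vstack([a, waverer, b])
        labels = ["a1", "a2", "a3", "w", "b1", "b2", "b3"]
        t = bootstrap_support(features, labels, n_boot=200, seed=5)
        clades = dendrogram_clades(t)
        w_support = min(
            n.support for c, n in clades.items() if "w" in c
        )
        other = [n.support for c, n in clades.items() if "w" not in c]
        assert w_support <= min(other)

    def test_supports_bounded_and_root_unlabelled(self, rng):
        features = rng.normal(size=(7, 12))
        t = bootstrap_support(features, [f"t{i}" for i in range(7)],
                              n_boot=30, seed=1)
        for node in t.preorder_node_iter():
            if node is t.seed_node:
                assert not hasattr(node, "support")
            elif not node.is_leaf():
                assert 0.0 <= node.support <= 100.0


class TestNewick:
    def test_round_trip(self):
        t = from_newick("((A:1,B:1)90:1,C:2);")
        s = to_newick(t)
        t2 = from_newick(s)
        labels = sorted(l.taxon.label for l in t2.leaf_node_iter())
        assert labels == ["A", "B", "C"]
        supports = [n.support for n in t2.preorder_node_iter()
                    if getattr(n, "support", None) is not None]
        assert supports == [90.0]

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="Newick"):
            from_newick("((A:1,B:1:2,C;")


class TestUltrametric:
    def test_dendrogram_rescaled_linearly(self, rng):
        pts = rng.normal(size=(6, 3))
        d = DistanceMatrix([f"t{i}" for i in range(6)], squareform(pdist(pts)))
        t = single_linkage_tree(d)
        heights_before = sorted(
            n.height for n in t.preorder_node_iter() if not n.is_leaf()
        )
        u = make_ultrametric(t, (0.0, 10.0))
        heights_after = sorted(
            n.height for n in u.preorder_node_iter() if not n.is_leaf()
        )
        factor = 10.0 / heights_before[-1]
        assert np.allclose(heights_after,
                           [h * factor for h in heights_before])

    def test_two_leaf_tree_root_at_interval_top(self):
        t = from_newick("(A:3,B:3);")
        t.is_rooted = True
        u = make_ultrametric(t, (0.0, 10.0))
        hts = node_heights(u)
        assert max(hts.values()) == pytest.approx(10.0)

    def test_nj_tree_rooted_on_outgroup_becomes_ultrametric(self, rng):
        d = random_additive_matrix(rng, 7)
        nj = neighbor_joining(d)
        u = make_ultrametric(nj, (0.0, 10.0), outgroup=d.labels[0])
        hts = node_heights(u)  # raises if not ultrametric
        assert max(hts.values()) == pytest.approx(10.0)
        # monotone: parent height >= child height
        for node in u.preorder_node_iter():
            for c in node.child_nodes():
                assert hts[node] >= hts[c] - 1e-9

    def test_unrooted_without_outgroup_rejected(self, rng):
        d = random_additive_matrix(rng, 5)
        nj = neighbor_joining(d)
        with pytest.raises(ValueError, match="outgroup"):
            make_ultrametric(nj, (0.0, 10.0))

    def test_missing_outgroup_label(self, rng):
        d = random_additive_matrix(rng, 5)
        with pytest.raises(ValueError, match="not found"):
            root_on_outgroup(neighbor_joining(d), "nope")


class TestPrune:
    def test_prune_does_not_mutate_original(self, rng):
        labels = [f"t{i}" for i in range(6)]
        t, _ = simulate_coalescent_tree(labels, rng)
        before = to_newick(t)
        pruned = prune_taxa(t, ["t0"])
        assert to_newick(t) == before
        assert sorted(l.taxon.label for l in pruned.leaf_node_iter()) == labels[1:]
        # original namespace intact: a second prune still works
        pruned2 = prune_taxa(t, ["t0"])
        assert sorted(l.taxon.label for l in pruned2.leaf_node_iter()) == labels[1:]
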