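import dendropy
import numpy as np
import pytest

from its2delimit.gmyc import (
    _Candidate,
    _GmycTree,
    branching_times,
    gmyc_multiple,
    gmyc_single,
    lr_test,
    node_support_akaike,
)
from its2delimit.synthetic import (
    simulate_coalescent_tree,
    simulate_species_coalescent_tree,
)
from its2delimit.trees import from_newick


def rooted(newick):
    t = from_newick(newick)
    t.is_rooted = True
    return t


class TestBranchingTimes:
    def test_two_leaf_tree(self):
        assert branching_times(rooted("(A:3,B:3);")).tolist() == [3.0]

    def test_balanced_four_leaf(self):
        t = rooted("((A:1,B:1):2,(C:1,D:1):2);")
        assert branching_times(t).tolist() == [3.0, 1.0, 1.0]

    def test_count_is_tips_minus_one(self, rng):
        for n in (4, 9, 15):
            t, _ = simulate_coalescent_tree([f"x{i}" for i in range(n)], rng)
            assert len(branching_times(t)) == n - 1

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            branching_times(rooted("((A:1,B:2):1,C:4);"))


class TestLrTest:
    def test_zero_statistic_gives_one(self):
        assert lr_test(-10.0, -10.0) == pytest.approx(1.0)

    def test_chi2_quantile(self):
        # 2*delta = 7.815 is the 5% point of chi-square with df=3
        assert lr_test(0.0, 7.815 / 2, df=3) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_statistic(self):
        ps = [lr_test(0.0, d / 2) for d in (0.5, 2.0, 8.0, 20.0)]
        assert ps == sorted(ps, reverse=True)

    def test_best_below_null_rejected(self):
        with pytest.raises(ValueError):
            lr_test(0.0, -1.0)


class TestSingleThreshold:
    def test_recovers_planted_species(self):
        rng = np.random.default_rng(5)
        t, truth = simulate_species_coalescent_tree(
            3, 8, rng, species_depth=10.0, ne=0.05
        )
        res = gmyc_single(t)
        assert res.n_ml_clusters == 3
        got = {frozenset(c) for c in res.clusters if len(c) >= 2}
        assert got == {frozenset(b) for b in truth}
        assert res.p_value < 0.05

    def test_single_population_not_rejected(self):
        rng = np.random.default_rng(0)
        t, _ = simulate_coalescent_tree([f"x{i}" for i in range(24)], rng)
        res = gmyc_single(t)
        assert res.p_value >= 0.05

    def test_best_never_below_null(self, rng):
        for _ in range(8):
            n = int(rng.integers(5, 20))
            t, _ = simulate_coalescent_tree([f"x{i}" for i in range(n)], rng)
            res = gmyc_single(t)
            assert res.best_loglik >= res.null_loglik - 1e-6
            assert 0.0 <= res.p_value <= 1.0
            assert sorted(x for c in res.clusters for x in c) == sorted(
                f"x{i}" for i in range(n)
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        t, _ = simulate_species_coalescent_tree(4, 6, rng, ne=0.05)
        res = gmyc_single(t)
        t2 = t.clone(depth=1)
        for e in t2.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * 4.2
        res2 = gmyc_single(t2)
        assert res2.n_ml_clusters == res.n_ml_clusters
        assert res2.lr_stat == pytest.approx(res.lr_stat, abs=1e-6)

    def test_too_small_tree_rejected(self):
        with pytest.raises(ValueError, match="3 tips"):
            gmyc_single(rooted("(A:1,B:1);"))

    def test_identical_tips_collapsed_and_restored(self):
        # C1 and C2 join at age zero: one haplotype, same cluster
        t = rooted("(((C1:0,C2:0):1,D:1):9,((A1:0.9,A2:0.9):0.1,B:1.0):9);")
        res = gmyc_single(t)
        tips = sorted(x for c in res.clusters for x in c)
        assert tips == ["A1", "A2", "B", "C1", "C2", "D"]
        cluster_of = {x: i for i, c in enumerate(res.clusters) for x in c}
        assert cluster_of["C1"] == cluster_of["C2"]


class TestMultipleThreshold:
    def test_single_threshold_data_keeps_comparable_aic(self):
        rng = np.random.default_rng(8)
        t, truth = simulate_species_coalescent_tree(
            4, 8, rng, species_depth=10.0, ne=0.05
        )
        s = gmyc_single(t)
        m = gmyc_multiple(t)
        assert abs(m.aic_best - s.aic_best) <= 2.0
        assert m.n_ml_clusters == len(truth)

    def test_two_depth_fixture_recovers_all_clusters(self):
        # two species pairs at very different divergence depths
        rng = np.random.default_rng(2)
        sub = {}
        for name, depth in (("a", 10.0), ("b", 10.0), ("c", 3.0), ("d", 3.0)):
            labels = [f"{name}{i}" for i in range(6)]
            tree, h = simulate_coalescent_tree(labels, rng, ne=0.04)
            sub[name] = (tree, h, labels)
        taxa = dendropy.TaxonNamespace(
            [l for (_, _, ls) in sub.values() for l in ls]
        )
        tree = dendropy.Tree(taxon_namespace=taxa)

        def graft(name):
            t, h, _ = sub[name]
            mapping = {}
            for nd in t.postorder_node_iter():
                new = dendropy.Node(
                    taxon=taxa.get_taxon(nd.taxon.label) if nd.is_leaf() else None
                )
                new.age_ = nd.age_
                for c in nd.child_nodes():
                    new.add_child(mapping[c])
                    mapping[c].edge.length = new.age_ - mapping[c].age_
                mapping[nd] = new
            return mapping[t.seed_node]

        def join(x, y, age):
            p = dendropy.Node()
            p.age_ = age
            for child in (x, y):
                p.add_child(child)
                child.edge.length = age - child.age_
            return p

        ab = join(graft("a"), graft("b"), 10.0)
        cd = join(graft("c"), graft("d"), 3.0)
        tree.seed_node = join(ab, cd, 14.0)
        tree.is_rooted = True

        res = gmyc_multiple(tree)
        got = {frozenset(c) for c in res.clusters if len(c) >= 2}
        expected = {frozenset(ls) for (_, _, ls) in sub.values()}
        assert got == expected

    def test_visited_set_contains_single_optimum(self):
        rng = np.random.default_rng(4)
        t, _ = simulate_species_coalescent_tree(3, 6, rng, ne=0.05)
        s = gmyc_single(t)
        m = gmyc_multiple(t)
        # the multiple-threshold search starts from the single optimum, so
        # it can never end with a worse AIC
        assert m.aic_best <= s.aic_best + 1e-9


class TestNodeSupport:
    def _gt(self):
        rng = np.random.default_rng(6)
        t, _ = simulate_species_coalescent_tree(3, 4, rng, ne=0.05)
        return _GmycTree(t)

    def _candidate(self, gt, inside, aic):
        c = _Candidate(
            roots=frozenset(), loglik=-aic / 2, lambda_div=1, p_div=1,
            lambda_coal=1, p_coal=1, n_params=0, inside=inside,
        )
        return c

    def test_single_candidate_gives_unit_support(self):
        gt = self._gt()
        inside = np.ones(gt.n_events, dtype=bool)
        sup = node_support_akaike([self._candidate(gt, inside, 10.0)], gt)
        assert all(v == pytest.approx(1.0) for v in sup.values())

    def test_two_equal_candidates_split_support(self):
        gt = self._gt()
        inside1 = np.zeros(gt.n_events, dtype=bool)
        inside1[0] = True
        inside2 = np.zeros(gt.n_events, dtype=bool)
        sup = node_support_akaike(
            [self._candidate(gt, inside1, 4.0), self._candidate(gt, inside2, 4.0)],
            gt,
        )
        key = frozenset(gt.leaf_labels[0])
        assert sup[key] == pytest.approx(0.5)

    def test_supports_bounded_by_one(self):
        rng = np.random.default_rng(9)
        t, _ = simulate_species_coalescent_tree(4, 5, rng, ne=0.05)
        res = gmyc_single(t)
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in res.node_support.values())

    def test_empty_candidate_set_rejected(self):
        gt = self._gt()
        with pytest.raises(ValueError):
            node_support_akaike([], gt)
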