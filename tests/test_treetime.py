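import numpy as np
import pytest
from scipy import stats

from disparitree import (InputError, NodeConstraint, StratRange, TimeScaleSpec,
                         Tree, build_tree, build_tree_set,
                         resolve_polytomies_random, sample_fossil_ages,
                         time_scale_equal)
from oracles import all_rooted_binary_topologies, as_tree, equal_scale_reference


class TestStratRange:
    def test_invariants(self):
        with pytest.raises(InputError):
            StratRange("x", older_bound=3.0, younger_bound=5.0)
        with pytest.raises(InputError):
            StratRange("x", older_bound=1.0, younger_bound=-0.5)
        assert StratRange("x", 0.0, 0.0).is_extant
        assert not StratRange("x", 5.0, 0.0).is_extant


class TestSampleFossilAges:
    def test_older_bound_is_exact_and_extant_zero(self):
        ranges = [StratRange("f", 100.5, 93.9), StratRange("e", 0.0, 0.0)]
        ages = sample_fossil_ages(ranges, "older_bound")
        assert ages == {"f": 100.5, "e": 0.0}
        ages_u = sample_fossil_ages(ranges, "uniform",
                                    np.random.default_rng(0))
        assert ages_u["e"] == 0.0
        assert 93.9 <= ages_u["f"] <= 100.5

    def test_uniform_mode_distribution(self, rng):
        r = StratRange("f", 10.0, 0.0)
        draws = np.array([sample_fossil_ages([r], "uniform", rng)["f"]
                          for _ in range(10_000)])
        assert stats.kstest(draws, "uniform", args=(0, 10)).pvalue > 0.001


class TestResolvePolytomies:
    def test_binary_tree_unchanged(self, rng):
        tree = build_tree((("A", "B"), ("C", "D")))
        out = resolve_polytomies_random(tree, rng)
        assert out.clades() == tree.clades()
        assert out.is_binary()

    def test_tip_conservation_and_clade_superset(self, rng):
        tree = Tree.from_newick("((A,B,C,D),E,(F,G));")
        out = resolve_polytomies_random(tree, rng)
        assert out.is_binary()
        assert sorted(out.tip_labels) == sorted(tree.tip_labels)
        assert tree.clades() <= out.clades()

    def test_trichotomy_gives_one_of_three_resolutions(self, rng):
        tree = Tree.from_newick("(A,B,C);")
        out = resolve_polytomies_random(tree, rng)
        cherries = [c for c in out.clades() if len(c) == 2]
        assert len(cherries) == 1
        assert cherries[0] in {frozenset("AB"), frozenset("AC"),
                               frozenset("BC")}


class TestTimeScaleEqual:
    def test_three_tip_worked_example(self):
        topo = build_tree((("A", "B"), "C"))
        tree = time_scale_equal(topo, {"A": 10.0, "B": 5.0, "C": 0.0},
                                vartime=1.0)
        assert tree.root.age == pytest.approx(11.0)
        for node in tree.preorder():
            if not node.is_root:
                assert node.parent.age - node.age > 0
        # inner node evenly splits the slack above tip A
        inner = tree.mrca(["A", "B"])
        assert inner.age == pytest.approx(10.5)

    def test_constraints_dominate_on_ultrametric_tree(self):
        topo = build_tree((("A", "B"), ("C", "D")))
        ages = {t: 0.0 for t in "ABCD"}
        constraints = [NodeConstraint(frozenset("AB"), 10.0),
                       NodeConstraint(frozenset("CD"), 12.0),
                       NodeConstraint(frozenset("ABCD"), 20.0)]
        tree = time_scale_equal(topo, ages, constraints, vartime=1.0)
        assert tree.mrca(["A", "B"]).age == pytest.approx(10.0)
        assert tree.mrca(["C", "D"]).age == pytest.approx(12.0)
        assert tree.root.age == pytest.approx(21.0)  # 20 + vartime

    def test_constraint_propagates_to_parent(self):
        # a constraint deeper than the stage-1 age of an ancestor must
        # push the ancestor back too
        topo = build_tree((("A", "B"), "C"))
        tree = time_scale_equal(topo, {"A": 1.0, "B": 0.0, "C": 0.0},
                                [NodeConstraint(frozenset("AB"), 50.0)],
                                vartime=1.0)
        assert tree.mrca(["A", "B"]).age >= 50.0
        assert tree.root.age == pytest.approx(51.0)

    def test_parent_always_older(self, rng):
        for _ in range(20):
            shape = (("A", ("B", "E")), ("C", "D"))
            ages = {t: float(rng.uniform(0, 20)) for t in "ABCDE"}
            tree = time_scale_equal(build_tree(shape), ages, vartime=1.0)
            for node in tree.preorder():
                if not node.is_root:
                    assert node.parent.age > node.age

    def test_polytomy_input_allowed(self, rng):
        topo = Tree.from_newick("(A,B,C,(D,E));")
        ages = {"A": 5.0, "B": 5.0, "C": 2.0, "D": 0.0, "E": 1.0}
        tree = time_scale_equal(topo, ages, vartime=1.0)
        for node in tree.preorder():
            if not node.is_root:
                assert node.parent.age > node.age

    def test_matches_reference_on_random_trees(self, rng):
        """Implementation agrees with the independently coded recursive
        three-stage procedure on random shapes, ages and constraints."""
        labels = list("ABCDE")
        shapes = list(all_rooted_binary_topologies(labels))
        pick = rng.choice(len(shapes), size=25, replace=False)
        for i in pick:
            tree = as_tree(shapes[i])
            ages = {t: float(np.round(rng.uniform(0, 15), 3))
                    for t in labels}
            constraints = []
            if rng.random() < 0.5:
                tips = rng.choice(labels, size=2, replace=False)
                constraints.append(
                    NodeConstraint(frozenset(tips), float(rng.uniform(0, 25))))
            scaled = time_scale_equal(
                tree, ages, constraints, vartime=1.0)
            ref = equal_scale_reference(
                tree, ages,
                [(c.tips, c.min_age) for c in constraints], vartime=1.0)
            for node in scaled.preorder():
                key = tuple(sorted(
                    t.label for t in Tree(node).tips())) if node.children \
                    else (node.label,)
                assert scaled_age_close(node.age, ref[key]), \
                    f"{key}: {node.age} vs {ref[key]}"

    def test_missing_tip_age_errors(self):
        with pytest.raises(InputError, match="B"):
            time_scale_equal(build_tree(("A", "B")), {"A": 1.0})


def scaled_age_close(a, b, tol=1e-9):
    return abs(a - b) <= tol


class TestBuildTreeSet:
    def topo_ranges(self):
        topo = Tree.from_newick("((A,B,C),(D,E));")
        ranges = [StratRange("A", 30.0, 20.0), StratRange("B", 15.0, 10.0),
                  StratRange("C", 0.0, 0.0), StratRange("D", 0.0, 0.0),
                  StratRange("E", 8.0, 2.0)]
        return topo, ranges

    def test_replicate_count_and_determinism(self):
        topo, ranges = self.topo_ranges()
        spec = TimeScaleSpec.tree_set(3, n_replicates=10, seed=42)
        trees1 = build_tree_set(topo, ranges, (), spec)
        trees2 = build_tree_set(topo, ranges, (), spec)
        assert len(trees1) == 10
        for t1, t2 in zip(trees1, trees2):
            a1 = {n.label: n.age for n in t1.preorder() if n.is_leaf}
            a2 = {n.label: n.age for n in t2.preorder() if n.is_leaf}
            assert a1 == a2  # bit-equal ages
            assert t1.clades() == t2.clades()

    def test_replicates_independent_of_total(self):
        topo, ranges = self.topo_ranges()
        few = build_tree_set(topo, ranges, (),
                             TimeScaleSpec.tree_set(3, n_replicates=3, seed=7))
        many = build_tree_set(topo, ranges, (),
                              TimeScaleSpec.tree_set(3, n_replicates=6, seed=7))
        for t1, t2 in zip(few, many):
            assert {n.label: n.age for n in t1.tips()} == \
                   {n.label: n.age for n in t2.tips()}

    def test_tree_set_recipes(self):
        topo, ranges = self.topo_ranges()
        t1 = build_tree_set(topo, ranges, (),
                            TimeScaleSpec.tree_set(1, n_replicates=2, seed=0))
        t2 = build_tree_set(topo, ranges, (),
                            TimeScaleSpec.tree_set(2, n_replicates=2, seed=0))
        t3 = build_tree_set(topo, ranges, (),
                            TimeScaleSpec.tree_set(3, n_replicates=2, seed=0))
        # set #1: resolved + oldest-bound ages
        for tree in t1:
            assert tree.is_binary()
            assert tree.find_tip("A").age == 30.0
        # set #2: polytomy kept, ages drawn within ranges
        for tree in t2:
            assert not tree.is_binary()
            assert 20.0 <= tree.find_tip("A").age <= 30.0
        # set #3: resolved + drawn ages
        for tree in t3:
            assert tree.is_binary()
            assert 20.0 <= tree.find_tip("A").age <= 30.0

    def test_constraint_satisfaction_across_replicates(self):
        topo, ranges = self.topo_ranges()
        coll = [[NodeConstraint(frozenset(["A", "B"]), 60.0)],
                [NodeConstraint(frozenset(["D", "E"]), 45.0)]]
        spec = TimeScaleSpec.tree_set(3, n_replicates=20, seed=3)
        log = []
        trees = build_tree_set(topo, ranges, coll, spec, log=log)
        for tree, entry in zip(trees, log):
            used = coll[entry["constraint_sample"]]
            for c in used:
                assert tree.mrca(c.tips).age >= c.min_age

    def test_root_to_tip_span_conserved_by_stage3(self):
        # with no constraints, root age = oldest tip + vartime, and each
        # tip's span root->tip is root age - tip age by construction
        topo, ranges = self.topo_ranges()
        spec = TimeScaleSpec.tree_set(1, n_replicates=5, seed=1)
        for tree in build_tree_set(topo, ranges, (), spec):
            assert tree.root.age == pytest.approx(31.0)

    def test_missing_range_errors(self):
        topo, _ = self.topo_ranges()
        with pytest.raises(InputError, match="E"):
            build_tree_set(topo, [StratRange(t, 0, 0) for t in "ABCD"], (),
                           TimeScaleSpec())
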