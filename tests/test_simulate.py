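import numpy as np
import pytest

from disparitree import (BirthDeathParams, BMParams, InputError,
                         LandmarkConfiguration, assign_strat_ranges,
                         generalized_procrustes, inject_polytomies,
                         make_dataset, read_tps, resolve_polytomies_random,
                         simulate_birth_death_tree, simulate_bm_traits,
                         simulate_landmark_shapes, write_tps)
from disparitree.simulate import default_mean_shape, regular_units


class TestBirthDeath:
    def test_pure_birth_tip_stop_is_ultrametric(self, rng):
        params = BirthDeathParams(birth=0.2, death=0.0, n_extant=10)
        tree = simulate_birth_death_tree(params, rng)
        assert tree.n_tips() == 10
        assert all(t.age == 0.0 for t in tree.tips())
        tree.validate_chronogram()

    def test_extinction_produces_fossil_tips(self, rng):
        params = BirthDeathParams(birth=0.15, death=0.1, n_extant=15)
        seen_fossil = False
        for _ in range(50):
            tree = simulate_birth_death_tree(params, rng)
            if any(t.age > 0 for t in tree.tips()):
                seen_fossil = True
                break
        assert seen_fossil

    def test_yule_expected_tip_count(self, rng):
        """Crown pure-birth process run to depth T: expected extant
        count is 2 e^(birth*T) (e^(birth*T) per initial lineage); the
        simulated mean must sit within 3 SE.  Survival conditioning is
        immaterial for a pure-birth process (no extinction)."""
        birth, T = 0.08, 10.0
        params = BirthDeathParams(birth=birth, death=0.0, depth=T)
        counts = np.array([
            sum(1 for t in simulate_birth_death_tree(params, rng).tips()
                if t.age == 0.0)
            for _ in range(500)], dtype=float)
        expected = 2 * np.exp(birth * T)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * se

    def test_reproducible_from_seed(self):
        params = BirthDeathParams(birth=0.1, death=0.05, n_extant=12)
        t1 = simulate_birth_death_tree(params, np.random.default_rng(3))
        t2 = simulate_birth_death_tree(params, np.random.default_rng(3))
        assert {n.label: n.age for n in t1.tips()} == \
               {n.label: n.age for n in t2.tips()}

    def test_hopeless_parameters_error(self, rng):
        params = BirthDeathParams(birth=0.01, death=5.0, n_extant=50,
                                  max_retries=5)
        with pytest.raises(InputError, match="extinction"):
            simulate_birth_death_tree(params, rng)


class TestBMTraits:
    def test_zero_rate_constant(self, rng):
        params = BirthDeathParams(birth=0.2, death=0.0, n_extant=8)
        tree = simulate_birth_death_tree(params, rng)
        tips, true_tree = simulate_bm_traits(
            tree, BMParams(rate=0.0, root_value=[3.0, -1.0], p=2), rng)
        for v in tips.values():
            np.testing.assert_array_equal(v, [3.0, -1.0])

    def test_variance_law_on_star_tree(self, rng):
        from disparitree.trees import Node, Tree

        T, n = 10.0, 400
        root = Node(age=T)
        for i in range(n):
            root.add_child(Node(f"t{i}", age=0.0))
        star = Tree(root)
        rate = 2.0
        variances = []
        for _ in range(30):
            tips, _ = simulate_bm_traits(star, BMParams(rate=rate, p=1), rng)
            variances.append(np.var([v[0] for v in tips.values()], ddof=1))
        variances = np.asarray(variances)
        se = variances.std(ddof=1) / np.sqrt(variances.size)
        assert abs(variances.mean() - rate * T) < 3 * se

    def test_covariance_equals_shared_path(self, rng):
        """cov(tip values) = rate * shared root-to-MRCA path length."""
        from disparitree import build_tree

        tree = build_tree((("A", "B"), "C"))
        tree.root.age = 10.0
        ab = tree.mrca(["A", "B"])
        ab.age = 4.0
        for t in tree.tips():
            t.age = 0.0
        pairs = []
        for _ in range(1000):
            tips, _ = simulate_bm_traits(tree, BMParams(rate=1.0, p=1), rng)
            pairs.append([tips["A"][0], tips["B"][0]])
        pairs = np.array(pairs)
        cov = np.cov(pairs.T)[0, 1]
        shared = tree.root.age - ab.age  # 6 Myr of common history
        assert abs(cov - shared) < 3 * np.sqrt(2 * (shared ** 2 + 100) / 1000)

    def test_true_internal_values_returned(self, rng):
        params = BirthDeathParams(birth=0.2, death=0.0, n_extant=6)
        tree = simulate_birth_death_tree(params, rng)
        tips, true_tree = simulate_bm_traits(tree, BMParams(rate=1.0, p=2),
                                             rng)
        for node in true_tree.preorder():
            assert node.traits is not None and node.traits.shape == (2,)


class TestLandmarkShapes:
    def test_zero_rate_identical_after_gpa(self, rng):
        params = BirthDeathParams(birth=0.2, death=0.0, n_extant=6)
        tree = simulate_birth_death_tree(params, rng)
        k = 8
        configs, _ = simulate_landmark_shapes(
            default_mean_shape(k), tree, BMParams(rate=0.0, p=2 * k), rng)
        # nuisance transforms differ even though shape does not
        assert not np.allclose(configs[0].coords, configs[1].coords)
        aligned, _ = generalized_procrustes(configs)
        for s in aligned[1:]:
            assert np.abs(s.coords - aligned[0].coords).max() < 1e-8

    def test_tps_round_trip(self, rng, tmp_path):
        params = BirthDeathParams(birth=0.2, death=0.0, n_extant=5)
        tree = simulate_birth_death_tree(params, rng)
        k = 6
        configs, _ = simulate_landmark_shapes(
            default_mean_shape(k), tree, BMParams(rate=1e-3, p=2 * k), rng)
        write_tps(tmp_path / "sim.tps", configs)
        back = read_tps(tmp_path / "sim.tps")
        for a, b in zip(configs, back):
            assert a.specimen_id == b.specimen_id
            np.testing.assert_allclose(a.coords, b.coords)

    def test_recovered_scores_track_generating_deviations(self, rng):
        """With small shape variance the leading PC scores of the
        aligned shapes are strongly linearly related to the generating
        BM deviations (canonical correlation > 0.9)."""
        from disparitree import principal_components
        from disparitree.trees import Node, Tree
        from sklearn.cross_decomposition import CCA

        root = Node(age=1.0)
        for i in range(100):
            root.add_child(Node(f"t{i}", age=0.0))
        star = Tree(root)
        k = 8
        configs, true_dev = simulate_landmark_shapes(
            default_mean_shape(k), star, BMParams(rate=1e-5, p=2 * k), rng)
        aligned, _ = generalized_procrustes(configs)
        space = principal_components(aligned)
        scores = space.scores[:, :3]
        truth = np.stack([true_dev[c.specimen_id] for c in configs])
        cca = CCA(n_components=1).fit(scores, truth)
        u, v = cca.transform(scores, truth)
        assert np.corrcoef(u[:, 0], v[:, 0])[0, 1] > 0.9


class TestStratAssignment:
    def test_unit_containment(self):
        from disparitree.trees import Node, Tree

        root = Node(age=9.0)
        root.add_child(Node("fossil", age=7.3))
        root.add_child(Node("recent", age=0.0))
        tree = Tree(root)
        ranges = assign_strat_ranges(tree, [(10.0, 5.0), (5.0, 0.0)])
        by_tip = {r.tip_id: r for r in ranges}
        assert (by_tip["fossil"].older_bound,
                by_tip["fossil"].younger_bound) == (10.0, 5.0)
        assert by_tip["recent"].is_extant

    def test_true_age_always_inside_assigned_range(self, rng):
        params = BirthDeathParams(birth=0.15, death=0.1, n_extant=15)
        tree = simulate_birth_death_tree(params, rng)
        units = regular_units(tree.root.age + 5, 5.0)
        for r in assign_strat_ranges(tree, units):
            true_age = tree.find_tip(r.tip_id).age
            assert r.younger_bound <= true_age <= r.older_bound

    def test_age_outside_units_errors(self):
        from disparitree.trees import Node, Tree

        root = Node(age=30.0)
        root.add_child(Node("a", age=25.0))
        root.add_child(Node("b", age=0.0))
        with pytest.raises(InputError, match="outside"):
            assign_strat_ranges(Tree(root), [(10.0, 0.0)])


class TestInjectPolytomies:
    def test_zero_fraction_unchanged(self, rng):
        params = BirthDeathParams(birth=0.2, death=0.0, n_extant=10)
        tree = simulate_birth_death_tree(params, rng)
        topo = inject_polytomies(tree, 0.0, rng)
        assert topo.is_binary()
        assert topo.clades() == tree.clades()

    def test_half_fraction_reduces_internal_nodes(self, rng):
        params = BirthDeathParams(birth=0.2, death=0.0, n_extant=20)
        tree = simulate_birth_death_tree(params, rng)
        topo = inject_polytomies(tree, 0.5, rng)
        assert len(topo.internal_nodes()) < 19
        assert sorted(topo.tip_labels) == sorted(tree.tip_labels)

    def test_resolution_restores_clade_superset(self, rng):
        params = BirthDeathParams(birth=0.2, death=0.0, n_extant=12)
        tree = simulate_birth_death_tree(params, rng)
        topo = inject_polytomies(tree, 0.4, rng)
        resolved = resolve_polytomies_random(topo, rng)
        assert resolved.is_binary()
        assert topo.clades() <= resolved.clades()


def test_default_dataset_is_reproducible_and_complete():
    ds1 = make_dataset(seed=5)
    ds2 = make_dataset(seed=5)
    assert ds1.true_tree.root.age == ds2.true_tree.root.age
    assert sorted(ds1.topology.tip_labels) == sorted(ds1.true_tree.tip_labels)
    assert len(ds1.ranges) == ds1.true_tree.n_tips()
    assert all(v.shape == (7,) for v in ds1.tip_traits.values())
    np.testing.assert_array_equal(ds1.tip_traits["t1"], ds2.tip_traits["t1"])
    assert sum(1 for t in ds1.true_tree.tips() if t.age == 0.0) == 40
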