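import numpy as np
import pytest

from quartetbm.distances import DistanceMatrix, is_additive
from quartetbm.genetree import true_best_matches
from quartetbm.inference import (bm_from_rooted_tree, epsilon_best_hits,
                                 midpoint_root, nj_midpoint_method,
                                 nj_unrooted, outgroup_species_pairs,
                                 quartet_best_matches, quartet_method,
                                 select_outgroups_rootside,
                                 theorem_incongruence_flag)
from quartetbm.noise import perturb_multiplicative
from quartetbm.species import simulate_dated_species_tree
from quartetbm.trees import PlantedTree

from conftest import make_scenario, random_length_tree


def small_matrix():
    # one focal gene x (species A), three candidates in species B
    labels = ["x", "b1", "b2", "b3"]
    d = np.array([[0.0, 1.0, 1.4, 1.6],
                  [1.0, 0.0, 0.5, 0.6],
                  [1.4, 0.5, 0.0, 0.4],
                  [1.6, 0.6, 0.4, 0.0]])
    color = {"x": "A", "b1": "B", "b2": "B", "b3": "B"}
    return DistanceMatrix(labels, d), color


class TestEpsilonMethod:
    def test_zero_epsilon_is_argmin(self):
        D, color = small_matrix()
        rel = epsilon_best_hits(D, color, 0.0)
        assert rel.out_set("x", color, "B") == {"b1"}

    def test_threshold_example(self):
        # distances (1.0, 1.4, 1.6), eps = 0.5 -> threshold 1.5
        D, color = small_matrix()
        rel = epsilon_best_hits(D, color, 0.5)
        assert rel.out_set("x", color, "B") == {"b1", "b2"}

    def test_large_epsilon_returns_everything(self):
        D, color = small_matrix()
        rel = epsilon_best_hits(D, color, 100.0)
        assert rel.out_set("x", color, "B") == {"b1", "b2", "b3"}

    def test_negative_epsilon_raises(self):
        D, color = small_matrix()
        with pytest.raises(ValueError):
            epsilon_best_hits(D, color, -0.1)


class TestNeighborJoining:
    def test_exact_recovery_on_additive_data(self, rng):
        for _ in range(5):
            t = random_length_tree(10, rng)
            D = t.path_distance_matrix()
            u = nj_unrooted(D)
            truth_splits = {frozenset(s) for s in t.unroot().splits()}
            nj_splits = {frozenset(s) for s in u.splits()}
            assert truth_splits == nj_splits  # Robinson-Foulds distance 0
            assert np.allclose(u.path_distance_matrix(D.labels).data,
                               D.data, atol=1e-8)

    def test_three_leaves(self):
        D = DistanceMatrix(list("abc"),
                           np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
        u = nj_unrooted(D)
        assert sorted(u.leaf_labels()) == ["a", "b", "c"]
        assert np.allclose(u.path_distance_matrix(list("abc")).data, D.data)

    def test_noisy_input_still_yields_a_tree(self, rng):
        t = random_length_tree(12, rng)
        D = perturb_multiplicative(t.path_distance_matrix(), 1.0, rng)
        u = nj_unrooted(D)
        assert sorted(u.leaf_labels()) == sorted(D.labels)
        # the matrix realised by any tree is additive
        assert is_additive(u.path_distance_matrix(D.labels), tol=1e-8)


class TestMidpointRooting:
    def test_two_leaves_root_at_edge_midpoint(self):
        t = PlantedTree.from_nested([("a", 0.4), ("b", 0.6)])
        rooted = midpoint_root(t.unroot())
        (a_child, b_child) = rooted.root.children
        lengths = sorted([a_child.length, b_child.length])
        assert lengths == [pytest.approx(0.5), pytest.approx(0.5)]

    def test_ultrametric_source_recovers_true_root(self, rng):
        cfg_tree = simulate_dated_species_tree(8, rng)
        for v in cfg_tree.preorder(include_planted=False):
            v.length = v.parent.tau - v.tau
        color = {lab: lab for lab in cfg_tree.leaf_labels()}  # 1 gene/species
        truth = true_best_matches(cfg_tree, color)
        rooted = midpoint_root(cfg_tree.unroot())
        assert bm_from_rooted_tree(rooted, color) == truth

    def test_rate_asymmetry_displaces_root_and_best_match(self):
        # paralogs evolving fast in opposite lineages: the midpoint root
        # lands inside the fast cherry and the best match flips
        t = PlantedTree.from_nested(
            [([("x", 0.1), ("y", 1.2)], 0.05),
             ([("xp", 1.0), ("yp", 0.1)], 0.05)])
        color = {"x": "red", "xp": "red", "y": "blue", "yp": "blue"}
        truth = true_best_matches(t, color)
        assert ("x", "y") in truth
        pred = bm_from_rooted_tree(midpoint_root(t.unroot()), color)
        assert ("x", "yp") in pred and ("x", "y") not in pred

    def test_identity_when_tree_is_correct(self, rng):
        scn, obs, color, D = make_scenario(rng)
        assert bm_from_rooted_tree(obs, color) == true_best_matches(obs, color)


class TestOutgroupSelection:
    def balanced_species_tree(self):
        # ((A,B),(C,D)) dated
        t = PlantedTree.from_nested([[ "A", "B" ], [ "C", "D" ]])
        t.planted_root.tau = 1.0
        t.root.tau = 0.8
        for c, tau in zip(t.root.children, (0.4, 0.5)):
            c.tau = tau
            for leaf in c.children:
                leaf.tau = 0.0
        return t

    def test_two_species_have_no_outgroups(self):
        S = simulate_dated_species_tree(2, 0)
        genes = {"s1": ["g1"], "s2": ["g2"]}
        assert select_outgroups_rootside(S, genes, "s1", "s2") == []

    def test_balanced_tree_rootside_candidates(self):
        S = self.balanced_species_tree()
        genes = {s: [s.lower() + "1", s.lower() + "2"] for s in "ABCD"}
        Z = select_outgroups_rootside(S, genes, "A", "B", cap=20)
        assert sorted(Z) == ["c1", "c2", "d1", "d2"]
        # below-cap sets are returned in full
        assert select_outgroups_rootside(S, genes, "A", "B", cap=2, seed=0)

    def test_closest_ranking(self):
        S = self.balanced_species_tree()
        genes = {s: [s.lower()] for s in "ABCD"}
        table = outgroup_species_pairs(S, genes, "closest")
        # for (C, D) the closest relative outgroups are A and B via the root
        assert set(table[frozenset(("C", "D"))]) == {"A", "B"}

    def test_same_species_pair_gets_outgroups(self):
        S = self.balanced_species_tree()
        genes = {s: [s.lower()] for s in "ABCD"}
        table = outgroup_species_pairs(S, genes, "rootside")
        assert table[frozenset(("A",))] == ["C", "D"] or \
            set(table[frozenset(("A",))]) == {"C", "D"}


class TestIncongruenceFilter:
    def species_tree(self):
        S = PlantedTree.from_nested([["A", "B"], ["C", "D"]])
        S.planted_root.tau = 1.0
        S.root.tau = 0.8
        for c, tau in zip(S.root.children, (0.4, 0.5)):
            c.tau = tau
            for leaf in c.children:
                leaf.tau = 0.0
        return S

    def test_species_tracking_genes_are_congruent(self):
        S = self.species_tree()
        gene_tree = PlantedTree.from_nested(
            [([("a", 0.2), ("b", 0.2)], 0.2), ([("c", 0.2), ("d", 0.2)], 0.2)])
        D = gene_tree.path_distance_matrix()
        color = {"a": "A", "b": "B", "c": "C", "d": "D"}
        assert not theorem_incongruence_flag(D, S, color, "a", "b", "c", "d")

    def test_preroot_duplication_is_flagged(self):
        # gene quartet (ac|bd) conflicts with species quartet (AB|CD)
        S = self.species_tree()
        gene_tree = PlantedTree.from_nested(
            [([("a", 0.2), ("c", 0.2)], 0.2), ([("b", 0.2), ("d", 0.2)], 0.2)])
        D = gene_tree.path_distance_matrix()
        color = {"a": "A", "b": "B", "c": "C", "d": "D"}
        assert theorem_incongruence_flag(D, S, color, "a", "b", "c", "d")

    def test_star_gene_quartet_is_congruent(self):
        S = self.species_tree()
        data = np.full((4, 4), 2.0)
        np.fill_diagonal(data, 0.0)
        D = DistanceMatrix(list("abcd"), data)
        color = {"a": "A", "b": "B", "c": "C", "d": "D"}
        assert not theorem_incongruence_flag(D, S, color, "a", "b", "c", "d")

    def test_bad_species_shape_raises(self):
        S = self.species_tree()
        D = DistanceMatrix(list("abcd"),
                           np.ones((4, 4)) - np.eye(4))
        color = {"a": "A", "b": "A", "c": "C", "d": "D"}
        with pytest.raises(ValueError):
            theorem_incongruence_flag(D, S, color, "a", "b", "c", "d")


class TestQuartetAlgorithm:
    def test_tied_candidates_return_whole_set(self):
        # both candidates hang below the same lca: complete digraph
        t = PlantedTree.from_nested(
            [("x", 0.3), ([("y1", 0.1), ("y2", 0.1)], 0.1), ("z", 0.9)])
        D = t.path_distance_matrix()
        color = {"x": "A", "y1": "B", "y2": "B", "z": "C"}
        out = quartet_best_matches(D, color, "x", ["y1", "y2"], ["z"])
        assert out == {"y1", "y2"}

    def test_strict_order_returns_singleton(self):
        # lca(x, y1) strictly below lca(x, y2)
        t = PlantedTree.from_nested(
            [([([("x", 0.1), ("y1", 0.1)], 0.1), ("y2", 0.2)], 0.1),
             ("z", 0.5)])
        D = t.path_distance_matrix()
        color = {"x": "A", "y1": "B", "y2": "B", "z": "C"}
        out = quartet_best_matches(D, color, "x", ["y1", "y2"], ["z"])
        assert out == {"y1"}
        truth = true_best_matches(t, color)
        assert truth.out_set("x", color, "B") == {"y1"}

    def test_single_candidate_is_trivial(self):
        D, color = small_matrix()
        assert quartet_best_matches(D, color, "x", ["b1"], []) == {"b1"}

    def test_empty_outgroups_raise(self):
        D, color = small_matrix()
        with pytest.raises(ValueError):
            quartet_best_matches(D, color, "x", ["b1", "b2"], [])

    def test_method_is_exact_on_additive_data(self, rng):
        for _ in range(5):
            scn, obs, color, D = make_scenario(rng, n_species=8)
            if scn.root_preimages > 2:
                continue
            truth = true_best_matches(obs, color)
            rel, evaluable = quartet_method(D, color, scn.species_tree,
                                            seed=rng)
            assert rel.restricted(color, evaluable) == \
                truth.restricted(color, evaluable)

    def test_closest_outgroups_also_work(self, rng):
        scn, obs, color, D = make_scenario(rng, n_species=8, dup=0.4,
                                           loss=0.4)
        truth = true_best_matches(obs, color)
        rel, evaluable = quartet_method(D, color, scn.species_tree,
                                        outgroups="closest", seed=rng)
        pred = rel.restricted(color, evaluable)
        want = truth.restricted(color, evaluable)
        # exactness is not guaranteed for closest outgroups, but on small
        # clean scenarios the overlap should be overwhelming
        assert len(pred.arcs & want.arcs) >= 0.9 * len(want.arcs)


class TestStudyHelpers:
    def test_nj_midpoint_pipeline_runs(self, rng):
        scn, obs, color, D = make_scenario(rng)
        rel = nj_midpoint_method(D, color)
        species = set(color.values())
        for x in color:
            for t in species - {color[x]}:
                assert rel.out_set(x, color, t)
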