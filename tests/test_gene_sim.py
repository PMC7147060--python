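import math

import numpy as np
import pytest

from quartetbm.genetree import (ExtinctFamilyError, count_ancient_duplications,
                                prune_to_observable, simulate_gene_tree,
                                true_best_matches)
from quartetbm.relations import BestMatchRelation
from quartetbm.species import simulate_dated_species_tree
from quartetbm.trees import PlantedTree, TreeNode

from conftest import make_scenario


def brute_force_best_matches(tree, color):
    """Oracle: compare lca(x, y) against lca(x, y') for every candidate."""
    labels = tree.leaf_labels()
    depths = tree.depths()
    rel = BestMatchRelation()
    for x in labels:
        for y in labels:
            if color[y] == color[x]:
                continue
            dxy = depths[tree.lca([x, y]).id]
            if all(dxy >= depths[tree.lca([x, yp]).id]
                   for yp in labels if color[yp] == color[y]):
                rel.add(x, y)
    return rel


class TestGillespie:
    def test_zero_rates_reproduce_species_tree(self, rng):
        S = simulate_dated_species_tree(9, rng)
        scn = simulate_gene_tree(S, 0.0, 0.0, 0.0, rng)
        assert sorted(scn.color.values()) == sorted(S.leaf_labels())
        assert scn.event_counts["duplication"] == 0
        assert scn.event_counts["loss"] == 0
        # one speciation vertex in T per inner vertex of S
        n_inner = sum(1 for v in S.preorder(False) if not v.is_leaf)
        assert scn.event_counts["speciation"] == n_inner
        assert scn.root_preimages == 1

    def test_loss_only_survival_probability(self, rng):
        # under pure loss at rate lam, a gene survives a root-to-leaf path
        # (duration 1) with probability exp(-lam); E[#extant] = 2 exp(-lam)
        S = simulate_dated_species_tree(2, rng)
        lam = 0.8
        counts = [len(simulate_gene_tree(S, 0.0, lam, 0.0, rng).color)
                  for _ in range(3000)]
        assert np.mean(counts) == pytest.approx(2 * math.exp(-lam), abs=0.05)

    def test_negative_rates_raise(self, rng):
        S = simulate_dated_species_tree(3, rng)
        with pytest.raises(ValueError):
            simulate_gene_tree(S, -0.1, 0.0, 0.0, rng)

    def test_timestamps_decrease_and_events_labelled(self, rng):
        scn, _, _, _ = make_scenario(rng, n_species=10)
        for v in scn.tree.preorder(include_planted=False):
            assert v.tau < v.parent.tau or (v.tau == 0.0 and v.parent.tau > 0)
            assert v.event in ("speciation", "duplication", "hgt", "loss",
                               "extant")

    def test_species_consistency_of_root_paths(self, rng):
        # without HGT every extant gene passes exactly through the
        # speciations on its species' root path
        scn, _, _, _ = make_scenario(rng, n_species=8)
        S = scn.species_tree
        for leaf in scn.tree.leaves():
            if leaf.event != "extant":
                continue
            passed = []
            node = leaf.parent
            while node is not None:
                if node.event == "speciation":
                    passed.append(node.mu)
                node = node.parent
            sp = S.find_leaf(scn.color[leaf.label])
            expected, anc = [], sp.parent
            while anc is not None and anc.parent is not None:
                expected.append(anc.id)
                anc = anc.parent
            assert passed == expected

    def test_hgt_never_lands_in_source_branch(self, rng):
        seen = 0
        for _ in range(30):
            S = simulate_dated_species_tree(8, rng)
            scn = simulate_gene_tree(S, 0.3, 0.2, 0.8, rng)
            for v in scn.tree.preorder(include_planted=False):
                if v.event == "hgt":
                    moved = [c for c in v.children if c.transferred]
                    assert len(moved) == 1
                    assert moved[0].sbranch != v.mu
                    seen += 1
        assert seen > 50


class TestObservableTree:
    def test_leaf_set_is_extant_genes(self, rng):
        scn, obs, color, _ = make_scenario(rng)
        assert sorted(obs.leaf_labels()) == sorted(scn.color)
        obs.validate()

    def test_lost_duplicate_leaves_no_trace(self):
        # hand-built: cherry species tree, duplication whose second copy
        # is fully lost; the observable tree contracts the duplication
        S = simulate_dated_species_tree(2, 5)
        scn = None
        rng = np.random.default_rng(0)
        for _ in range(500):
            cand = simulate_gene_tree(S, 0.9, 0.9, 0.0, rng)
            dups = cand.duplication_nodes()
            if not dups or not cand.color:
                continue
            obs, _ = prune_to_observable(cand)
            kept_events = {v.event for v in obs.preorder(False)
                           if not v.is_leaf}
            # any retained inner vertex must still have >= 2 children
            assert all(len(v.children) >= 2 for v in obs.preorder(False)
                       if not v.is_leaf)
            scn = cand
            break
        assert scn is not None

    def test_extinct_family_raises(self, rng):
        S = simulate_dated_species_tree(2, rng)
        for _ in range(200):
            try:
                scn = simulate_gene_tree(S, 0.0, 5.0, 0.0, rng)
            except ExtinctFamilyError:
                continue
            if not scn.color:
                with pytest.raises(ExtinctFamilyError):
                    prune_to_observable(scn)
                return
        pytest.skip("no extinct family drawn")  # pragma: no cover


class TestTruth:
    def test_single_gene_per_species_is_complete_bipartite(self, rng):
        S = simulate_dated_species_tree(6, rng)
        scn = simulate_gene_tree(S, 0.0, 0.0, 0.0, rng)
        obs, color = prune_to_observable(scn)
        rel = true_best_matches(obs, color)
        n = len(color)
        assert len(rel.arcs) == n * (n - 1)

    def test_rate_asymmetry_example(self):
        # gene tree where lca(x, y) precedes lca(x, y'): only y is the
        # best match even though y' may be more similar
        t = PlantedTree.from_nested(
            [([("x", 0.1), ("y", 1.2)], 0.05),
             ([("xp", 1.0), ("yp", 0.1)], 0.05)])
        color = {"x": "red", "xp": "red", "y": "blue", "yp": "blue"}
        rel = true_best_matches(t, color)
        assert ("x", "y") in rel and ("x", "yp") not in rel

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            scn, obs, color, _ = make_scenario(rng, n_species=6)
            assert true_best_matches(obs, color) == \
                brute_force_best_matches(obs, color)


class TestAncientDuplications:
    def test_zero_without_duplications(self, rng):
        S = simulate_dated_species_tree(5, rng)
        scn = simulate_gene_tree(S, 0.0, 0.0, 0.0, rng)
        assert count_ancient_duplications(scn) == 0

    def test_preroot_duplications_are_counted(self, rng):
        found = 0
        for _ in range(200):
            S = simulate_dated_species_tree(4, rng)
            scn = simulate_gene_tree(S, 1.0, 0.0, 0.0, rng)
            n_preroot = sum(1 for v in scn.duplication_nodes()
                            if v.tau > S.root.tau)
            assert count_ancient_duplications(scn) == n_preroot
            found += n_preroot > 0
        assert found > 5

    def test_root_preimages_count_lineages_at_first_speciation(self, rng):
        # no losses: preimages = 1 + number of pre-root duplications
        for _ in range(100):
            S = simulate_dated_species_tree(4, rng)
            scn = simulate_gene_tree(S, 0.8, 0.0, 0.0, rng)
            assert scn.root_preimages == 1 + count_ancient_duplications(scn)


class TestSerialization:
    def test_write_scenario_bundle(self, rng, tmp_path):
        scn, _, _, _ = make_scenario(rng, n_species=5, dup=1.0, loss=1.0)
        from quartetbm.genetree import write_scenario
        out = str(tmp_path / "scn")
        write_scenario(scn, out)
        import os
        files = sorted(os.listdir(out))
        assert files == ["colors.tsv", "genes.nwk", "reconciliation.tsv",
                         "species.nwk"]
        genes_nwk = open(os.path.join(out, "genes.nwk")).read()
        has_loss = any(v.event == "loss" for v in scn.tree.leaves())
        assert ("*LOSS*" in genes_nwk) == has_loss
        table = open(os.path.join(out, "reconciliation.tsv")).read()
        assert table.startswith("vertex\tevent\tmu\ttau")
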