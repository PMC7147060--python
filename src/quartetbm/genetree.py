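"""Gillespie simulation of gene family evolution inside a dated species tree.

Genes evolve along the branches of a dated species tree ``S`` under
constant per-gene rates of duplication (D), loss (L) and horizontal
transfer (H).  Speciation times are fixed by ``S`` and held in temporal
order; when the sampled waiting time crosses a speciation, the clock is
advanced to the speciation, the gene content is copied into the daughter
branches, and a fresh waiting time is drawn (the exponential clock is
memoryless).  The result is an *extended* gene tree: every vertex carries
a timestamp, an event label, and its reconciliation image in ``S``
(speciations map to species vertices; D/H vertices and loss leaves map to
species branches).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .relations import BestMatchRelation, best_matches_from_tree
from .trees import PlantedTree, TreeNode

__all__ = ["GeneScenario", "ExtinctFamilyError", "simulate_gene_tree",
           "prune_to_observable", "true_best_matches",
           "count_ancient_duplications", "write_scenario"]


class ExtinctFamilyError(ValueError):
    """Raised when no extant gene survives to the present."""


@dataclass
class GeneScenario:
    """Simulation truth bundle: species tree, extended gene tree, colours.

    ``color`` maps extant gene labels to species labels.  ``root_preimages``
    is the number of gene lineages alive at the first speciation, i.e. the
    number of gene-tree vertices reconciled onto the species root.
    """

    species_tree: PlantedTree
    tree: PlantedTree
    color: dict[str, str]
    root_preimages: int
    event_counts: dict[str, int] = field(default_factory=dict)

    def species_node(self, vid: int) -> TreeNode:
        for v in self.species_tree.preorder():
            if v.id == vid:
                return v
        raise KeyError(vid)

    def extant_labels(self) -> list[str]:
        return sorted(self.color)

    def duplication_nodes(self) -> list[TreeNode]:
        return [v for v in self.tree.preorder(include_planted=False)
                if v.event == "duplication"]


@dataclass
class _Lineage:
    node: TreeNode        # open edge hangs below this vertex
    branch: int           # species branch = id of the branch's lower vertex
    transferred: bool = False


def simulate_gene_tree(S: PlantedTree, dup_rate: float, loss_rate: float,
                       hgt_rate: float = 0.0,
                       seed: Union[int, np.random.Generator, None] = None
                       ) -> GeneScenario:
    """Simulate one extended gene tree along the dated species tree ``S``.

    The family starts as a single gene on the planted branch at ``tau = 1``.
    Event selection and waiting times follow the standard two-draw
    Gillespie scheme with total rate ``R = n_genes * (D + L + H)``.  The
    HGT landing site is uniform over the species branches alive at the
    event time, excluding the source branch; if no other branch is alive
    the transfer is skipped as a null event.
    """
    if min(dup_rate, loss_rate, hgt_rate) < 0:
        raise ValueError("rates must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    S.validate(dated=True)

    snodes = {v.id: v for v in S.preorder()}
    rho = S.root
    speciations = sorted(
        (v for v in S.preorder(include_planted=False) if not v.is_leaf),
        key=lambda v: v.tau, reverse=True)
    spec_children = {v.id: [c.id for c in v.children] for v in speciations}

    counter = itertools.count(1)
    gene_counter = itertools.count(1)
    loss_counter = itertools.count(1)

    planted = TreeNode(0, tau=S.planted_root.tau, event="planted")
    planted.mu = S.planted_root.id

    lineages: list[_Lineage] = [_Lineage(planted, rho.id)]
    alive_branches: set[int] = {rho.id}
    per_gene = dup_rate + loss_rate + hgt_rate
    tau = S.planted_root.tau
    spec_idx = 0
    root_preimages = 0
    counts = {"duplication": 0, "loss": 0, "hgt": 0, "speciation": 0}

    def attach(lin: _Lineage, t: float, event: str, mu, label=None) -> TreeNode:
        node = TreeNode(next(counter), label=label, tau=t, event=event)
        node.sbranch = lin.branch
        node.transferred = lin.transferred
        node.mu = mu
        lin.node.add_child(node)
        return node

    while True:
        R = len(lineages) * per_gene
        if R > 0 and lineages:
            t_event = tau - math.log(1.0 / rng.random()) / R
        else:
            t_event = -math.inf
        next_spec = speciations[spec_idx] if spec_idx < len(speciations) else None

        if next_spec is not None and t_event <= next_spec.tau:
            # speciation happens first; clock advances, waiting time redrawn
            tau = next_spec.tau
            spec_idx += 1
            w = next_spec.id
            affected = [l for l in lineages if l.branch == w]
            alive_branches.discard(w)
            alive_branches.update(spec_children[w])
            if w == rho.id:
                root_preimages = len(affected)
            for lin in affected:
                lineages.remove(lin)
                node = attach(lin, tau, "speciation", mu=w)
                counts["speciation"] += 1
                for child_branch in spec_children[w]:
                    lineages.append(_Lineage(node, child_branch))
            continue

        if t_event <= 0.0 or not lineages:
            break

        tau = t_event
        lin = lineages[rng.integers(len(lineages))]
        u = rng.random() * per_gene
        if u < dup_rate:
            node = attach(lin, tau, "duplication", mu=lin.branch)
            counts["duplication"] += 1
            lineages.remove(lin)
            lineages.append(_Lineage(node, lin.branch))
            lineages.append(_Lineage(node, lin.branch))
        elif u < dup_rate + loss_rate:
            attach(lin, tau, "loss", mu=lin.branch,
                   label=f"loss{next(loss_counter)}")
            counts["loss"] += 1
            lineages.remove(lin)
        else:
            targets = sorted(alive_branches - {lin.branch})
            if not targets:
                continue  # no landing site available; null event
            node = attach(lin, tau, "hgt", mu=lin.branch)
            counts["hgt"] += 1
            lineages.remove(lin)
            lineages.append(_Lineage(node, lin.branch))
            lineages.append(_Lineage(
                node, int(targets[rng.integers(len(targets))]),
                transferred=True))

    color: dict[str, str] = {}
    for lin in lineages:
        species = snodes[lin.branch]
        label = f"g{next(gene_counter)}"
        attach(lin, 0.0, "extant", mu=lin.branch, label=label)
        color[label] = species.label

    if not planted.children:
        raise ExtinctFamilyError("root lineage lost before any event")
    tree = PlantedTree(planted)
    return GeneScenario(S, tree, color, root_preimages, counts)


def prune_to_observable(scn: GeneScenario) -> tuple[PlantedTree, dict[str, str]]:
    """Observable gene tree: drop all-loss subtrees, contract unary vertices.

    Contracted-edge lengths are summed when lengths are set, so the leaf
    distance matrix of the observable tree equals the one induced by the
    full extended tree.
    """
    extant = scn.extant_labels()
    if not extant:
        raise ExtinctFamilyError("gene family extinct: no observable tree")
    return scn.tree.restrict(extant), dict(scn.color)


def true_best_matches(tree: PlantedTree,
                      color: dict[str, str]) -> BestMatchRelation:
    """Best matches read off the (observable) gene tree: the ground truth."""
    return best_matches_from_tree(tree, color)


def write_scenario(scn: GeneScenario, directory: str) -> None:
    """Serialise a scenario: two Newick files plus a reconciliation table.

    Loss leaves are tagged ``*LOSS*`` in the gene Newick.  The TSV lists,
    per gene-tree vertex: id, event label, reconciliation image (species
    vertex for speciations, species branch otherwise) and timestamp.
    """
    import os

    from .io import write_color_map, write_newick

    os.makedirs(directory, exist_ok=True)
    write_newick(scn.species_tree, os.path.join(directory, "species.nwk"))
    tagged = scn.tree.copy()
    for v in tagged.leaves():
        if v.event == "loss":
            v.label = f"{v.label}*LOSS*"
    write_newick(tagged, os.path.join(directory, "genes.nwk"))
    write_color_map(scn.color, os.path.join(directory, "colors.tsv"))
    with open(os.path.join(directory, "reconciliation.tsv"), "w") as fh:
        fh.write("vertex\tevent\tmu\ttau\n")
        for v in scn.tree.preorder(include_planted=False):
            fh.write(f"{v.id}\t{v.event or 'extant'}\t{v.mu}\t{v.tau:.10g}\n")


def count_ancient_duplications(scn: GeneScenario, u: Optional[TreeNode] = None
                               ) -> int:
    """Number of duplication vertices reconciled strictly above ``u``.

    ``u`` defaults to the species root, in which case this counts
    duplications on the planted species branch (pre-dating the first
    speciation).  A duplication on species branch ``b`` lies above ``u``
    iff ``u`` is at or below the lower end of ``b``.
    """
    S = scn.species_tree
    if u is None:
        u = S.root
    count = 0
    snodes = {v.id: v for v in S.preorder()}
    for v in scn.duplication_nodes():
        lower = snodes[v.mu]
        if lower is u or S.is_strict_ancestor(u, lower):
            count += 1
    return count
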