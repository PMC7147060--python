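"""Simulation of dated, planted species trees.

Topologies come from an innovation-driven branching process (species as
feature sets; gaining a novel feature or losing one to reach an unseen
genotype founds a new lineage), which yields imbalanced, realistic shapes.
A Yule (pure-birth) generator is available as an alternative.  Dates are
assigned top-down on [0, 1] so that the expected time elapsed along an
edge ``uv`` equals ``tau(u)`` divided by the number of edges on a path
from ``u`` through ``v`` down to a sampled leaf.
"""

from __future__ import annotations

import itertools
from typing import Optional, Union

import numpy as np

from .trees import PlantedTree, TreeNode

__all__ = ["simulate_species_topology", "date_species_tree",
           "simulate_dated_species_tree"]

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _branch_leaf(leaf: TreeNode, counter, new_label: str) -> TreeNode:
    """Split a leaf into an inner vertex with the old species and a new one."""
    cont = TreeNode(next(counter), label=leaf.label)
    new = TreeNode(next(counter), label=new_label)
    leaf.label = None
    leaf.add_child(cont)
    leaf.add_child(new)
    return new


def simulate_species_topology(n_species: int, seed: RngLike = None,
                              model: str = "innovation",
                              innovation_loss_prob: float = 0.5) -> PlantedTree:
    """Random planted species topology with ``n_species`` leaves.

    ``model`` is ``"innovation"`` (default) or ``"yule"``.  Leaves are
    labelled ``s1 .. sN`` in order of appearance.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(seed)
    counter = itertools.count(1)

    planted = TreeNode(0)
    first = TreeNode(next(counter), label="s1")
    planted.add_child(first)
    tree = PlantedTree(planted)
    leaves: dict[str, TreeNode] = {"s1": first}
    label_counter = itertools.count(2)

    if model == "yule":
        while len(leaves) < n_species:
            sp = str(rng.choice(sorted(leaves)))
            new_label = f"s{next(label_counter)}"
            new = _branch_leaf(leaves[sp], counter, new_label)
            leaves[sp] = leaves[sp].children[0]
            leaves[new_label] = new
        return tree

    if model != "innovation":
        raise ValueError(f"unknown topology model {model!r}")

    features: dict[str, frozenset] = {"s1": frozenset([0])}
    feature_counter = itertools.count(1)
    while len(leaves) < n_species:
        sp = str(rng.choice(sorted(leaves)))
        fs = features[sp]
        if rng.random() >= innovation_loss_prob:
            new_set = fs | {next(feature_counter)}
        else:
            if len(fs) < 2:
                continue
            lost = rng.choice(sorted(fs))
            new_set = fs - {lost}
            if new_set in features.values():
                continue
        new_label = f"s{next(label_counter)}"
        new = _branch_leaf(leaves[sp], counter, new_label)
        leaves[sp] = leaves[sp].children[0]
        leaves[new_label] = new
        features[new_label] = new_set
    return tree


def date_species_tree(S: PlantedTree, seed: RngLike = None) -> PlantedTree:
    """Assign dates ``tau`` on [0, 1] to a planted species topology.

    The planted root gets ``tau = 1``, leaves ``tau = 0``.  For an inner
    child ``v`` of ``u``, a leaf ``x`` below ``v`` is drawn uniformly, ``k``
    counts the speciations strictly between ``v`` and ``x``, and
    ``tau(v) = tau(u) * (1 - r / (k + 2))`` with ``r ~ Uniform(0, 2)``;
    since ``r < 2``, inner dates stay strictly positive.  Edge lengths are
    set to the date differences.
    """
    rng = _rng(seed)
    tree = S.copy()
    tree.planted_root.tau = 1.0

    leaves_below: dict[int, list[TreeNode]] = {}
    for v in tree.postorder(include_planted=False):
        leaves_below[v.id] = ([v] if v.is_leaf else
                              [l for c in v.children for l in leaves_below[c.id]])

    depths = tree.depths()
    for u in tree.preorder():
        if u.tau is None:
            continue
        for v in u.children:
            if v.is_leaf:
                v.tau = 0.0
            else:
                pool = leaves_below[v.id]
                x = pool[rng.integers(len(pool))]
                # inner vertices strictly between v and x
                k = depths[x.id] - depths[v.id] - 1
                r = rng.uniform(0.0, 2.0)
                v.tau = u.tau * (1.0 - r / (k + 2))
            v.length = u.tau - v.tau
    return tree


def simulate_dated_species_tree(n_species: int, seed: RngLike = None,
                                model: str = "innovation") -> PlantedTree:
    rng = _rng(seed)
    topo = simulate_species_topology(n_species, rng, model=model)
    return date_species_tree(topo, rng)
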