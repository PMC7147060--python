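"""The best-match relation and its computation from a rooted gene tree.

A gene ``y`` in species ``t`` is a *best match* of ``x`` (written
``x -> y``) if no other gene of species ``t`` has a lower last common
ancestor with ``x``.  Only cross-species arcs are stored; within one
species the relation is trivial.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .trees import PlantedTree

__all__ = ["BestMatchRelation", "lca_depth_matrix", "best_matches_from_tree"]


class BestMatchRelation:
    """Directed relation over extant genes, stored as a set of (x, y) arcs."""

    def __init__(self, arcs: Iterable[tuple[str, str]] = ()):
        self.arcs = set(arcs)

    def add(self, x: str, y: str) -> None:
        self.arcs.add((x, y))

    def __contains__(self, arc) -> bool:
        return tuple(arc) in self.arcs

    def __len__(self) -> int:
        return len(self.arcs)

    def __eq__(self, other) -> bool:
        return isinstance(other, BestMatchRelation) and self.arcs == other.arcs

    def __iter__(self):
        return iter(sorted(self.arcs))

    def restricted(self, color: dict[str, str],
                   species_pairs: set[frozenset]) -> "BestMatchRelation":
        """Keep arcs whose unordered species pair is in ``species_pairs``."""
        return BestMatchRelation(
            (x, y) for x, y in self.arcs
            if frozenset((color[x], color[y])) in species_pairs)

    def out_set(self, x: str, color: dict[str, str], species: str) -> set:
        return {y for (a, y) in self.arcs if a == x and color[y] == species}


def lca_depth_matrix(tree: PlantedTree, labels: list[str]) -> np.ndarray:
    """Edge-count depth (from the planted root) of lca(x, y) per leaf pair.

    For a fixed leaf ``x`` the vertices ``lca(x, y)`` all lie on the path
    from ``x`` to the root, so a deeper lca means a lower (more recent)
    ancestor; comparing depths therefore compares ancestors.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    mat = np.zeros((n, n), dtype=int)
    depths = tree.depths()

    def collect(node) -> np.ndarray:
        if node.is_leaf:
            i = idx[node.label]
            mat[i, i] = depths[node.id]
            return np.array([i], dtype=int)
        groups = [collect(c) for c in node.children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                mat[np.ix_(groups[a], groups[b])] = depths[node.id]
                mat[np.ix_(groups[b], groups[a])] = depths[node.id]
        return np.concatenate(groups)

    collect(tree.root)
    return mat


def best_matches_from_tree(tree: PlantedTree,
                           color: dict[str, str]) -> BestMatchRelation:
    """All best matches read off a rooted gene tree (the truth operation)."""
    labels = tree.leaf_labels()
    depth = lca_depth_matrix(tree, labels)
    by_species: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_species.setdefault(color[lab], []).append(i)
    groups = {s: np.array(ix) for s, ix in by_species.items()}
    rel = BestMatchRelation()
    for i, x in enumerate(labels):
        sx = color[x]
        for t, ix in groups.items():
            if t == sx:
                continue
            row = depth[i, ix]
            best = row.max()
            for j in ix[row == best]:
                rel.add(x, labels[j])
    return rel
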