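"""Planted (rooted) and unrooted phylogenetic trees.

A *planted* tree carries an artificial root ``0`` above the conventional
root :math:`\\rho`; the extra edge represents the ancestral lineage before
the first branching event, which is where pre-root gene duplications live.
Vertices optionally carry dates ``tau`` (time before present, in [0, 1])
and edges carry lengths ``length`` (expected substitutions per site,
stored on the child vertex).
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Iterator, Optional

import networkx as nx
import numpy as np

__all__ = ["TreeNode", "PlantedTree", "UnrootedTree"]


class TreeNode:
    """A vertex of a :class:`PlantedTree`.

    The edge to the parent is stored on the child: ``length`` is its length
    (``None`` if unset), ``sbranch`` an optional annotation naming the
    species-tree branch the edge is embedded in (used by the gene-tree
    simulator).
    """

    __slots__ = ("id", "parent", "children", "label", "tau", "length",
                 "event", "sbranch", "transferred", "mu")

    def __init__(self, id: int, label: Optional[str] = None,
                 tau: Optional[float] = None, length: Optional[float] = None,
                 event: Optional[str] = None):
        self.id = id
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []
        self.label = label
        self.tau = tau
        self.length = length
        self.event = event          # speciation / duplication / hgt / loss / extant
        self.sbranch = None         # species branch harbouring the edge above
        self.transferred = False    # set on the moved copy of an HGT event
        self.mu = None              # reconciliation image (species vertex/branch id)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id}, label={self.label!r}, event={self.event!r})"


class PlantedTree:
    """Rooted tree with a planted root of out-degree one.

    ``planted_root`` is the artificial vertex ``0``; its single child is the
    conventional root.  All traversals and leaf bookkeeping exclude the
    planted root from degree-two suppression.
    """

    def __init__(self, planted_root: TreeNode):
        if len(planted_root.children) != 1:
            raise ValueError("planted root must have exactly one child")
        self.planted_root = planted_root

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_nested(cls, spec, lengths: bool = True) -> "PlantedTree":
        """Build a tree from nested tuples/lists of leaf labels.

        ``spec`` is either a leaf label (str) or a sequence of child specs;
        each element may be ``(subspec, length)`` when ``lengths`` is True.
        Mainly used in tests and doc examples.
        """
        counter = itertools.count(1)

        def build(node_spec):
            length = None
            if isinstance(node_spec, tuple) and len(node_spec) == 2 \
                    and isinstance(node_spec[1], (int, float)):
                node_spec, length = node_spec
            if isinstance(node_spec, str):
                return TreeNode(next(counter), label=node_spec, length=length)
            node = TreeNode(next(counter), length=length)
            for child_spec in node_spec:
                node.add_child(build(child_spec))
            return node

        planted = TreeNode(0)
        planted.add_child(build(spec))
        return cls(planted)

    def copy(self) -> "PlantedTree":
        mapping: dict[int, TreeNode] = {}

        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.id, label=node.label, tau=node.tau,
                         length=node.length, event=node.event)
            c.sbranch = node.sbranch
            c.transferred = node.transferred
            c.mu = node.mu
            mapping[node.id] = c
            for child in node.children:
                c.add_child(clone(child))
            return c

        return PlantedTree(clone(self.planted_root))

    # -- basic structure ------------------------------------------------------

    @property
    def root(self) -> TreeNode:
        """The conventional root (single child of the planted root)."""
        return self.planted_root.children[0]

    def preorder(self, include_planted: bool = True) -> Iterator[TreeNode]:
        stack = [self.planted_root if include_planted else self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self, include_planted: bool = True) -> Iterator[TreeNode]:
        out = list(self.preorder(include_planted))
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [v for v in self.preorder(include_planted=False) if v.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [v.label for v in self.leaves()]

    def find_leaf(self, label: str) -> TreeNode:
        for v in self.leaves():
            if v.label == label:
                return v
        raise KeyError(f"unknown leaf label: {label!r}")

    def _leaf_map(self) -> dict[str, TreeNode]:
        m = {}
        for v in self.leaves():
            if v.label in m:
                raise ValueError(f"duplicate leaf label {v.label!r}")
            m[v.label] = v
        return m

    def depths(self) -> dict[int, int]:
        """Edge-count depth of every vertex (planted root at depth 0)."""
        d = {self.planted_root.id: 0}
        for v in self.preorder():
            if v.parent is not None:
                d[v.id] = d[v.parent.id] + 1
        return d

    # -- lca machinery --------------------------------------------------------

    def lca(self, labels: Iterable[str]) -> TreeNode:
        """Last common ancestor of a nonempty set of leaves.

        The lca is the unique ``\\preceq``-minimal vertex above all of the
        given leaves.
        """
        labels = list(labels)
        if not labels:
            raise ValueError("lca of an empty leaf set is undefined")
        lmap = self._leaf_map()
        try:
            nodes = [lmap[l] for l in labels]
        except KeyError as exc:
            raise KeyError(f"unknown leaf label: {exc.args[0]!r}") from None
        depths = self.depths()
        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            while depths[a.id] > depths[b.id]:
                a = a.parent
            while depths[b.id] > depths[a.id]:
                b = b.parent
            while a is not b:
                a, b = a.parent, b.parent
            cur = a
        return cur

    def is_strict_ancestor(self, u: TreeNode, v: TreeNode) -> bool:
        """True iff ``v`` lies strictly above ``u`` (``u`` strictly precedes ``v``)."""
        node = u.parent
        while node is not None:
            if node is v:
                return True
            node = node.parent
        return False

    # -- restriction and unrooting -------------------------------------------

    def restrict(self, labels: Iterable[str]) -> "PlantedTree":
        """Restriction T[L'] to a subset of leaves.

        Keeps the vertices on root-to-leaf paths of the retained leaves and
        suppresses the resulting degree-two vertices, summing edge lengths so
        that pairwise leaf distances are preserved.  The planted root is
        always retained.
        """
        labels = set(labels)
        if not labels:
            raise ValueError("cannot restrict to an empty leaf set")
        lmap = self._leaf_map()
        unknown = labels - set(lmap)
        if unknown:
            raise KeyError(f"unknown leaf label(s): {sorted(unknown)}")

        tree = self.copy()

        def prune(node: TreeNode) -> Optional[TreeNode]:
            """Return the pruned/suppressed copy of ``node``'s subtree."""
            if node.is_leaf:
                return node if node.label in labels else None
            kept = []
            for child in node.children:
                sub = prune(child)
                if sub is not None:
                    kept.append(sub)
            if not kept:
                return None
            if len(kept) == 1:
                # suppress this vertex; pass edge length up
                (sub,) = kept
                if sub.length is not None and node.length is not None:
                    sub.length = sub.length + node.length
                elif node.length is not None and sub.length is None:
                    sub.length = node.length
                sub.parent = None
                return sub
            node.children = []
            for sub in kept:
                node.add_child(sub)
            return node

        new_root = prune(tree.root)
        if new_root is None:  # pragma: no cover - guarded by label check
            raise ValueError("restriction removed all leaves")
        planted = TreeNode(tree.planted_root.id, tau=tree.planted_root.tau)
        planted.add_child(new_root)
        return PlantedTree(planted)

    def unroot(self) -> "UnrootedTree":
        """Drop the planted edge; contract the root if it has two children.

        Pairwise leaf distances are preserved exactly: when the root
        :math:`\\rho` is binary, the merged edge gets the sum of the two
        incident lengths.
        """
        if len(self.leaves()) < 2:
            raise ValueError("unrooting requires at least 2 leaves")
        g = nx.Graph()
        labels = {}
        root = self.root
        for v in self.preorder(include_planted=False):
            if v.is_leaf:
                labels[v.id] = v.label
            for c in v.children:
                g.add_edge(v.id, c.id, length=c.length)
        if len(root.children) == 2:
            a, b = root.children
            la, lb = a.length, b.length
            merged = None if (la is None or lb is None) else la + lb
            g.remove_node(root.id)
            g.add_edge(a.id, b.id, length=merged)
        return UnrootedTree(g, labels)

    # -- distances ------------------------------------------------------------

    def path_distance_matrix(self, labels: Optional[list[str]] = None):
        """Additive leaf-to-leaf distance matrix from the edge lengths.

        ``d(x, y)`` is the sum of edge lengths along the unique path between
        the leaves; the planted edge never lies on such a path.
        """
        from .distances import DistanceMatrix

        lmap = self._leaf_map()
        if labels is None:
            labels = self.leaf_labels()
        for v in self.preorder(include_planted=False):
            if v is not self.root and v.length is None:
                raise ValueError("edge lengths must be set on all edges")
        n = len(labels)
        mat = np.zeros((n, n))
        # adjacency over the unplanted part
        adj: dict[int, list[tuple[int, float]]] = {}
        for v in self.preorder(include_planted=False):
            for c in v.children:
                adj.setdefault(v.id, []).append((c.id, c.length))
                adj.setdefault(c.id, []).append((v.id, c.length))
        idx = {lab: i for i, lab in enumerate(labels)}
        for lab in labels:
            start = lmap[lab].id
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for w, le in adj.get(u, ()):
                    if w not in dist:
                        dist[w] = dist[u] + le
                        stack.append(w)
            for other in labels:
                mat[idx[lab], idx[other]] = dist[lmap[other].id]
        mat = (mat + mat.T) / 2.0  # exact symmetry
        np.fill_diagonal(mat, 0.0)
        return DistanceMatrix(labels, mat)

    # -- validation -----------------------------------------------------------

    def validate(self, dated: bool = False) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if len(self.planted_root.children) != 1:
            raise ValueError("planted root must have exactly one child")
        for v in self.preorder(include_planted=False):
            if not v.is_leaf and len(v.children) < 2:
                raise ValueError(f"inner vertex {v.id} has fewer than 2 children")
            if dated:
                if v.tau is None:
                    raise ValueError(f"vertex {v.id} lacks a date")
                if v.parent is not None and v.parent.tau is not None \
                        and not v.tau < v.parent.tau:
                    raise ValueError("dates must strictly decrease toward the leaves")

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder(include_planted=False))


class UnrootedTree:
    """Unrooted tree as an undirected graph with edge lengths.

    No degree-two vertices occur; leaves are the degree-one vertices and
    carry labels.
    """

    def __init__(self, graph: nx.Graph, labels: dict[int, str]):
        self.graph = graph
        self.labels = dict(labels)
        for node in graph.nodes:
            if graph.degree(node) == 2:
                raise ValueError(f"degree-2 vertex {node} in unrooted tree")
            if graph.degree(node) <= 1 and node not in self.labels:
                raise ValueError(f"unlabelled leaf {node}")

    def leaf_ids(self) -> list[int]:
        return [v for v in self.graph.nodes if self.graph.degree(v) <= 1]

    def leaf_labels(self) -> list[str]:
        return [self.labels[v] for v in self.leaf_ids()]

    def path_distance_matrix(self, labels: Optional[list[str]] = None):
        from .distances import DistanceMatrix

        by_label = {lab: v for v, lab in self.labels.items()}
        if labels is None:
            labels = sorted(by_label)
        n = len(labels)
        mat = np.zeros((n, n))
        for i, lab in enumerate(labels):
            dist = nx.single_source_dijkstra_path_length(
                self.graph, by_label[lab], weight="length")
            for j, other in enumerate(labels):
                mat[i, j] = dist[by_label[other]]
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 0.0)
        return DistanceMatrix(labels, mat)

    def splits(self) -> list[tuple[frozenset, frozenset]]:
        """Leaf bipartitions induced by removing each edge."""
        out = []
        all_leaves = frozenset(self.labels.values())
        for u, v in self.graph.edges:
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = nx.node_connected_component(g, u)
            left = frozenset(self.labels[w] for w in side if w in self.labels)
            out.append((left, all_leaves - left))
        return out
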