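"""Best-match inference from distances: three strategies.

* **epsilon-best-hits**: all genes within a factor ``1 + epsilon`` of the
  smallest distance per target species (the classical reciprocal-best-hit
  relaxation).  Exact only under a molecular clock.
* **NJ + midpoint rooting**: reconstruct the unrooted tree (exact for
  additive data), root it at the midpoint of the longest leaf path, read
  best matches off the rooted tree.  Isolates rooting errors caused by
  rate asymmetries.
* **quartet method**: for a focal gene ``x`` and candidate set ``Y`` in a
  target species, call the quartet topology of ``(x, y', y'', z)`` for
  outgroup genes ``z`` chosen with the help of the species tree.  With a
  trusted outgroup a quartet translates into an order between
  ``lca(x, y')`` and ``lca(x, y'')``; the arcs are collected in an
  auxiliary digraph whose sink strongly connected component is the
  best-match set.  Outgroup species are taken from the other side of the
  species root (``rootside``) or from the closest relative outgroups
  filtered by a gene/species quartet incongruence test (``closest``),
  incongruence being a certificate of an ancient duplication.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence, Union

import networkx as nx
import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .distances import DistanceMatrix, infer_quartet, quartet_calls_vs_outgroups
from .relations import BestMatchRelation, best_matches_from_tree
from .trees import PlantedTree, TreeNode, UnrootedTree

__all__ = ["epsilon_best_hits", "nj_unrooted", "midpoint_root",
           "bm_from_rooted_tree", "select_outgroups_rootside",
           "select_outgroups_closest", "theorem_incongruence_flag",
           "quartet_best_matches", "quartet_method", "outgroup_species_pairs"]

logger = logging.getLogger(__name__)

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# epsilon-best-hits

def epsilon_best_hits(D: DistanceMatrix, color: dict[str, str],
                      epsilon: float,
                      f_tol: float = 1e-9) -> BestMatchRelation:
    """Almost-best hits: ``d(x, y) <= (1 + eps) * min_{y'} d(x, y')``.

    ``f_tol`` is a relative floating-point margin on the threshold so that
    mathematically exact ties (e.g. ultrametric data summed in different
    orders) are kept together.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    groups: dict[str, np.ndarray] = {}
    for lab in D.labels:
        groups.setdefault(color[lab], []).append(D.index[lab])
    groups = {s: np.asarray(ix) for s, ix in groups.items()}
    rel = BestMatchRelation()
    for x in D.labels:
        i = D.index[x]
        for t, ix in groups.items():
            if t == color[x]:
                continue
            row = D.data[i, ix]
            thr = (1.0 + epsilon) * row.min()
            thr += f_tol * max(1.0, thr)
            for j in ix[row <= thr]:
                rel.add(x, D.labels[j])
    return rel


# ---------------------------------------------------------------------------
# NJ + midpoint rooting

def nj_unrooted(D: DistanceMatrix) -> UnrootedTree:
    """Neighbor joining; exact topology and lengths for additive input.

    Negative branch-length estimates (possible on noisy input) are clamped
    to zero, which only affects the placement of the midpoint root
    downstream, never the topology.
    """
    if len(D) < 3:
        g = nx.Graph()
        labels = {i: lab for i, lab in enumerate(D.labels)}
        if len(D) == 2:
            g.add_edge(0, 1, length=float(D.data[0, 1]))
        else:
            g.add_node(0)
        return UnrootedTree(g, labels)
    sk_tree = _skbio_nj(_SkbioDM(D.data, ids=D.labels))
    g = nx.Graph()
    labels: dict[int, str] = {}
    counter = [0]

    def conv(node, parent_id):
        counter[0] += 1
        nid = counter[0]
        if node.is_tip():
            labels[nid] = node.name
        if parent_id is not None:
            length = max(0.0, node.length or 0.0)
            g.add_edge(parent_id, nid, length=length)
        for child in node.children:
            conv(child, nid)
        return nid

    conv(sk_tree, None)
    # skbio roots the NJ tree at a degree-2 vertex; contract it
    for node in list(g.nodes):
        if g.degree(node) == 2 and node not in labels:
            a, b = g.neighbors(node)
            length = g[node][a]["length"] + g[node][b]["length"]
            g.remove_node(node)
            g.add_edge(a, b, length=length)
    return UnrootedTree(g, labels)


def _farthest(U: UnrootedTree, start: int) -> tuple[int, float, dict]:
    dist = nx.single_source_dijkstra_path_length(U.graph, start, weight="length")
    leaf_d = {v: dist[v] for v in U.leaf_ids()}
    far = max(leaf_d, key=leaf_d.get)
    return far, leaf_d[far], dist


def midpoint_root(U: UnrootedTree) -> PlantedTree:
    """Root at the midpoint of a longest leaf-to-leaf path.

    If the midpoint falls inside an edge the edge is subdivided; if it
    falls on a vertex that vertex becomes the root.  A planted root is
    added above.
    """
    leaf_ids = U.leaf_ids()
    if len(leaf_ids) == 1:
        only = leaf_ids[0]
        planted = TreeNode(0)
        planted.add_child(TreeNode(1, label=U.labels[only]))
        return PlantedTree(planted)
    a, _, _ = _farthest(U, leaf_ids[0])
    b, diameter, dist_a = _farthest(U, a)
    if diameter <= 0:
        logger.warning("zero-diameter tree; rooting at an arbitrary vertex")
    path = nx.shortest_path(U.graph, a, b, weight="length")
    half = diameter / 2.0
    g = U.graph.copy()
    root_vertex = None
    for u, v in zip(path, path[1:]):
        du, dv = dist_a[u], dist_a[v]
        if abs(du - half) < 1e-12:
            root_vertex = u
            break
        if du < half < dv:
            length = g[u][v]["length"]
            g.remove_edge(u, v)
            mid = max(g.nodes) + 1
            g.add_edge(u, mid, length=half - du)
            g.add_edge(mid, v, length=dv - half)
            root_vertex = mid
            break
    if root_vertex is None:
        root_vertex = b if abs(dist_a[b] - half) < 1e-12 else path[0]

    counter = [0]

    def build(vertex, parent_vertex) -> TreeNode:
        counter[0] += 1
        node = TreeNode(counter[0], label=U.labels.get(vertex))
        if parent_vertex is not None:
            node.length = g[parent_vertex][vertex]["length"]
        for nb in g.neighbors(vertex):
            if nb != parent_vertex:
                node.add_child(build(nb, vertex))
        return node

    planted = TreeNode(0)
    planted.add_child(build(root_vertex, None))
    return PlantedTree(planted)


def bm_from_rooted_tree(tree: PlantedTree,
                        color: dict[str, str]) -> BestMatchRelation:
    """Best matches read off a reconstructed rooted tree."""
    return best_matches_from_tree(tree, color)


def nj_midpoint_method(D: DistanceMatrix,
                       color: dict[str, str]) -> BestMatchRelation:
    return bm_from_rooted_tree(midpoint_root(nj_unrooted(D)), color)


# ---------------------------------------------------------------------------
# outgroup selection

def _species_index(S: PlantedTree):
    nodes = {v.id: v for v in S.preorder()}
    leaf_by_label = {v.label: v for v in S.leaves()}
    depths = S.depths()
    # root path (ids, bottom-up) per species label
    paths = {}
    for lab, leaf in leaf_by_label.items():
        p, node = [], leaf
        while node is not None:
            p.append(node.id)
            node = node.parent
        paths[lab] = p
    return nodes, leaf_by_label, depths, paths


def _lca_id(paths: dict, depths: dict, labels: Sequence[str]) -> int:
    common = set(paths[labels[0]])
    for lab in labels[1:]:
        common &= set(paths[lab])
    return max(common, key=lambda i: depths[i])


def outgroup_species_pairs(S: PlantedTree, genes_by_species: dict[str, list],
                           strategy: str = "rootside") -> dict[frozenset, list]:
    """Map each unordered species pair to its outgroup *species* list.

    ``rootside``: species ``z`` with ``lca(z, lca(A, B))`` at the species
    root, i.e. on the other side of the root than ``lca(A, B)``.
    ``closest``: all relative outgroups (``lca(A, B)`` strictly below
    ``lca(A, B, z)``), ordered from the closest (deepest joint lca) to the
    most distant.  Only species that actually contain genes are returned.
    """
    nodes, leaf_by_label, depths, paths = _species_index(S)
    present = [s for s, genes in genes_by_species.items() if genes]
    out: dict[frozenset, list] = {}
    root_id = S.root.id
    for i, A in enumerate(present):
        for B in present[i:]:
            key = frozenset((A, B))
            lca_ab = _lca_id(paths, depths, [A, B]) if A != B \
                else leaf_by_label[A].id
            cands = []
            for Z in present:
                if Z in (A, B):
                    continue
                joint = _lca_id(paths, depths, [A, B, Z]) if A != B else \
                    _lca_id(paths, depths, [A, Z])
                if joint == lca_ab:
                    continue  # z below or beside: not a relative outgroup
                if strategy == "rootside" and joint != root_id:
                    continue
                cands.append((depths[joint], Z))
            cands.sort(key=lambda t: (-t[0], t[1]))
            out[key] = [z for _, z in cands]
    return out


def _sample_pool(species: Sequence[str], genes_by_species: dict[str, list],
                 cap: int, rng: np.random.Generator) -> list[str]:
    pool = sorted(g for z in species for g in genes_by_species[z])
    if len(pool) <= cap:
        return pool
    return sorted(rng.choice(pool, size=cap, replace=False))


def select_outgroups_rootside(S: PlantedTree, genes_by_species: dict[str, list],
                              A: str, B: str, cap: int = 20,
                              seed: RngLike = None) -> list[str]:
    """Outgroup genes from species on the other side of the species root."""
    rng = _rng(seed)
    table = outgroup_species_pairs(S, genes_by_species, "rootside")
    species = table.get(frozenset((A, B)), [])
    return _sample_pool(species, genes_by_species, cap, rng)


def theorem_incongruence_flag(D: DistanceMatrix, S: PlantedTree,
                              color: dict[str, str], a: str, b: str,
                              c: str, d: str,
                              rel_tol: float = 1e-9) -> bool:
    """Gene/species quartet incongruence certifies an ancient duplication.

    Requires four genes in four distinct species forming the species
    quartet ``(s(a) s(b) | s(c) s(d))`` with both cherries strictly below
    their joint lca.  Returns True iff the gene quartet pairs ``a`` with
    ``c`` or with ``d`` (incongruent); a congruent or star gene quartet
    gives False.
    """
    sp = [color[g] for g in (a, b, c, d)]
    if len(set(sp)) != 4:
        raise ValueError("genes must reside in four pairwise distinct species")
    nodes, leaf_by_label, depths, paths = _species_index(S)
    u = _lca_id(paths, depths, sp)
    v1 = _lca_id(paths, depths, sp[:2])
    v2 = _lca_id(paths, depths, sp[2:])
    if v1 == u or v2 == u:
        raise ValueError("species quartet (ab|cd) with both cherries strictly "
                         "below the joint lca is required")
    call = infer_quartet(D, a, b, c, d, rel_tol)
    return call.pairs_with(a, c) or call.pairs_with(a, d)


def select_outgroups_closest(S: PlantedTree, genes_by_species: dict[str, list],
                             A: str, B: str, D: DistanceMatrix,
                             color: dict[str, str],
                             apply_filter: bool = True, cap: int = 20,
                             budget: int = 50,
                             seed: RngLike = None) -> list[str]:
    """Closest relative outgroups, filtered by the incongruence test.

    Candidate species are ranked by the depth of their joint lca with
    ``lca(A, B)`` (closest first).  For each candidate gene ``z`` up to
    ``budget`` quartets ``(x, y, z, z2)`` with ``x`` from ``A``, ``y`` from
    ``B`` and a partner outgroup ``z2`` from a different outgroup species
    are tested; a single incongruence flags ``z``.  If everything is
    filtered away, rootside selection is used as a fallback.
    """
    rng = _rng(seed)
    table = outgroup_species_pairs(S, genes_by_species, "closest")
    return _closest_genes(table.get(frozenset((A, B)), []), S,
                          genes_by_species, A, B, D, color, apply_filter,
                          cap, budget, rng)


def _closest_genes(species_ranked: list[str], S: PlantedTree,
                   genes_by_species: dict[str, list], A: str, B: str,
                   D: DistanceMatrix, color: dict[str, str],
                   apply_filter: bool, cap: int, budget: int,
                   rng: np.random.Generator,
                   rootside_species: Optional[list[str]] = None) -> list[str]:
    if not species_ranked:
        return []
    nodes, leaf_by_label, depths, paths = _species_index(S)

    chosen: list[str] = []
    genes_a = sorted(genes_by_species.get(A, []))
    genes_b = sorted(genes_by_species.get(B, []))
    for z_species in species_ranked:
        for z in sorted(genes_by_species[z_species]):
            if len(chosen) >= cap:
                break
            flagged = False
            if apply_filter and genes_a and genes_b:
                partners = [(z2s, g) for z2s in species_ranked
                            if z2s != z_species
                            for g in genes_by_species[z2s]]
                tests = 0
                while partners and tests < budget and not flagged:
                    z2s, z2 = partners[rng.integers(len(partners))]
                    x = genes_a[rng.integers(len(genes_a))]
                    y = genes_b[rng.integers(len(genes_b))] if A != B else None
                    if y is None or len({A, B, z_species, z2s}) != 4:
                        break
                    joint_z = _lca_id(paths, depths, [z_species, z2s])
                    joint_all = _lca_id(paths, depths, [A, B, z_species, z2s])
                    lca_ab = _lca_id(paths, depths, [A, B])
                    if joint_z == joint_all or lca_ab == joint_all:
                        break  # species quartet not of the required shape
                    tests += 1
                    if theorem_incongruence_flag(D, S, color, x, y, z, z2):
                        flagged = True
            if not flagged:
                chosen.append(z)
        if len(chosen) >= cap:
            break
    if not chosen:
        logger.info("all closest outgroups filtered for (%s, %s); "
                    "falling back to rootside selection", A, B)
        if rootside_species is not None:
            return _sample_pool(rootside_species, genes_by_species, cap, rng)
        return select_outgroups_rootside(S, genes_by_species, A, B, cap, rng)
    return chosen


# ---------------------------------------------------------------------------
# Algorithm 1: auxiliary digraph and its sink component

def _aggregate(calls: np.ndarray, mode: str) -> int:
    """Combine per-outgroup quartet codes into one code.

    Codes: 0 = (x y1 | y2 z), 1 = (x y2 | y1 z), 2 = (x z | y1 y2),
    -1 = star.  Returns the aggregated code, with 2 standing for
    "equality" (both arcs) and -1 for "no information" (mode ``omit``
    inserts nothing; other modes treat it like equality).
    """
    resolved = calls[calls >= 0]
    if resolved.size == 0:
        return -1 if mode == "omit" else 2
    counts = np.bincount(resolved, minlength=3)
    if mode == "default":
        # star votes count toward equality
        star = np.count_nonzero(calls < 0)
        votes = np.array([counts[0], counts[1], counts[2] + star])
    else:
        votes = counts
    top = votes.max()
    winners = np.flatnonzero(votes == top)
    if len(winners) > 1:
        return -1 if mode == "omit" else 2
    return int(winners[0])


def quartet_best_matches(D: Optional[DistanceMatrix], color: dict[str, str],
                         x: str, Y: Sequence[str], Z: Sequence[str],
                         rel_tol: float = 1e-9, mode: str = "default",
                         quartet_codes: Optional[Callable] = None) -> set[str]:
    """Best matches of ``x`` within candidate set ``Y`` given outgroups ``Z``.

    For every unordered pair in ``Y`` the quartet on ``(x, y', y'', z)``
    is called for each outgroup and aggregated; the call translates into
    lca order and hence into arcs of the auxiliary digraph (arcs point
    from the gene with the larger lca toward the smaller).  The answer is
    the union of sink strongly connected components -- unique under exact
    data, where the components are cliques.

    ``quartet_codes(x, y1, y2, Z) -> int array`` may replace the
    distance-based calls (e.g. quartet mapping on sequences).
    """
    Y = list(Y)
    if len(Y) == 1:
        return set(Y)
    if not Z:
        raise ValueError("outgroup set must be nonempty")
    if quartet_codes is None:
        if D is None:
            raise ValueError("need a distance matrix or a quartet source")
        def quartet_codes(x, y1, y2, zs):
            return quartet_calls_vs_outgroups(D, x, y1, y2, zs, rel_tol)

    m = len(Y)
    arcs = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            code = _aggregate(np.asarray(quartet_codes(x, Y[i], Y[j], Z)),
                              mode)
            if code == 0:        # lca(x,y_i) below lca(x,y_j)
                arcs[j, i] = True
            elif code == 1:
                arcs[i, j] = True
            elif code == 2:      # equality
                arcs[i, j] = arcs[j, i] = True
            # code -1 in omit mode: no arc
    return {Y[i] for i in np.flatnonzero(_sink_scc_union(arcs))}


def _batch_codes(d: np.ndarray, xi: np.ndarray, y1: int, y2: int,
                 zi: np.ndarray, rel_tol: float) -> np.ndarray:
    """Quartet codes for all (x, y1, y2, z), x in ``xi``, z in ``zi``."""
    s0 = d[xi, y1][:, None] + d[y2, zi][None, :]
    s1 = d[xi, y2][:, None] + d[y1, zi][None, :]
    s2 = d[np.ix_(xi, zi)] + d[y1, y2]
    sums = np.stack([s0, s1, s2])                 # (3, nx, nz)
    winner = sums.argmin(axis=0)
    part = np.partition(sums, 1, axis=0)
    margin = rel_tol * sums.max(axis=0)
    resolved = (part[1] - part[0]) > margin
    return np.where(resolved, winner, -1)


def _aggregate_rows(codes: np.ndarray, mode: str) -> np.ndarray:
    """Row-wise version of :func:`_aggregate` for a (nx, nz) code array."""
    c0 = (codes == 0).sum(axis=1)
    c1 = (codes == 1).sum(axis=1)
    c2 = (codes == 2).sum(axis=1)
    star = (codes == -1).sum(axis=1)
    votes = np.stack([c0, c1, c2 + star if mode == "default" else c2])
    top = votes.max(axis=0)
    tie = (votes == top).sum(axis=0) > 1
    out = votes.argmax(axis=0)
    none = votes.sum(axis=0) == 0
    if mode == "omit":
        return np.where(tie | none, -1, out)
    return np.where(tie | none, 2, out)


def _sink_scc_union(arcs: np.ndarray) -> np.ndarray:
    """Boolean mask of vertices lying in sink strongly connected components.

    ``arcs`` is the m x m adjacency matrix of the auxiliary digraph; the
    reachability closure is computed by repeated boolean squaring (m is
    the number of candidate genes, typically tiny).  A vertex belongs to
    a sink component iff everything it reaches also reaches it back.
    """
    m = arcs.shape[0]
    reach = arcs | np.eye(m, dtype=bool)
    while True:
        nxt = reach | (reach @ reach)
        if np.array_equal(nxt, reach):
            break
        reach = nxt
    return np.all(~reach | reach.T, axis=1)


def quartet_method(D: DistanceMatrix, color: dict[str, str], S: PlantedTree,
                   outgroups: str = "rootside", cap: int = 20,
                   mode: str = "default", rel_tol: float = 1e-9,
                   apply_filter: Optional[bool] = None,
                   seed: RngLike = None,
                   quartet_codes: Optional[Callable] = None
                   ) -> tuple[BestMatchRelation, set[frozenset]]:
    """Run the quartet approach for every gene and target species.

    Returns the inferred relation together with the set of *evaluable*
    unordered species pairs, i.e. those for which outgroup genes could be
    assigned; pairs without outgroups are skipped.
    """
    rng = _rng(seed)
    if apply_filter is None:
        apply_filter = outgroups == "closest"
    genes_by_species: dict[str, list] = {}
    for g, s in color.items():
        genes_by_species.setdefault(s, []).append(g)

    if outgroups not in ("rootside", "closest"):
        raise ValueError(f"unknown outgroup strategy {outgroups!r}")
    species = sorted(genes_by_species)
    table = outgroup_species_pairs(S, genes_by_species, outgroups)
    rootside_table = table if outgroups == "rootside" else \
        outgroup_species_pairs(S, genes_by_species, "rootside")
    z_cache: dict[frozenset, list] = {}
    for i, A in enumerate(species):
        for B in species[i + 1:]:
            key = frozenset((A, B))
            if outgroups == "rootside":
                z_cache[key] = _sample_pool(table.get(key, []),
                                            genes_by_species, cap, rng)
            else:
                z_cache[key] = _closest_genes(
                    table.get(key, []), S, genes_by_species, A, B, D, color,
                    apply_filter, cap, 50, rng,
                    rootside_species=rootside_table.get(key, []))

    evaluable = {key for key, zs in z_cache.items() if zs}
    rel = BestMatchRelation()
    if quartet_codes is not None:
        # generic (e.g. sequence-based) quartet source: per-gene path
        for x in sorted(color):
            sx = color[x]
            for t in species:
                if t == sx:
                    continue
                Z = z_cache.get(frozenset((sx, t)), [])
                if not Z:
                    continue
                Y = sorted(genes_by_species[t])
                for y in quartet_best_matches(D, color, x, Y, Z, rel_tol,
                                              mode, quartet_codes):
                    rel.add(x, y)
        return rel, evaluable

    # distance-based fast path: batch all focal genes of a species at once
    d = D.data
    for sx in species:
        X = sorted(genes_by_species[sx])
        xi = np.array([D.index[g] for g in X])
        for t in species:
            if t == sx:
                continue
            Z = z_cache.get(frozenset((sx, t)), [])
            if not Z:
                continue
            Y = sorted(genes_by_species[t])
            if len(Y) == 1:
                for x in X:
                    rel.add(x, Y[0])
                continue
            zi = np.array([D.index[g] for g in Z])
            yi = [D.index[g] for g in Y]
            m = len(Y)
            arcs = np.zeros((len(X), m, m), dtype=bool)
            for i in range(m):
                for j in range(i + 1, m):
                    codes = _batch_codes(d, xi, yi[i], yi[j], zi, rel_tol)
                    agg = _aggregate_rows(codes, mode)
                    arcs[agg == 0, j, i] = True      # lca(x,yi) is lower
                    arcs[agg == 1, i, j] = True
                    both = agg == 2
                    arcs[both, i, j] = True
                    arcs[both, j, i] = True
            for k, x in enumerate(X):
                best = _sink_scc_union(arcs[k])
                for i in np.flatnonzero(best):
                    rel.add(x, Y[i])
    return rel, evaluable
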