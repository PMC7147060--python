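"""Lineage- and paralog-specific evolution rates and additive distances.

Two layers produce the edge lengths of the gene tree.  A *baseline* rate
per species branch models lineage effects (population size, generation
time): the planted branch gets the mean rate and each child branch draws
a lognormal rate whose log-variance scales with the branch duration and
whose mean equals the parent branch's rate.  On top of this, gene-tree
edges are marked *conserved* (relative rate 1) or *divergent* (relative
rate > 1, Gamma-distributed) according to the fate of paralogs after each
duplication -- functional conservation, subfunctionalization or
neofunctionalization -- with a reversion to the conserved state for the
last surviving copy in a species.  The length of a gene-tree edge is the
baseline rate of its host species branch times the time integral of its
piecewise-constant relative rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .distances import DistanceMatrix
from .genetree import GeneScenario, prune_to_observable
from .trees import PlantedTree, TreeNode

__all__ = ["RateConfig", "RateSchedule", "baseline_rates",
           "assign_gene_rates", "edge_lengths", "scenario_distance_matrix"]

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class RateConfig:
    """Parameters of the rate model.

    ``mean_rate``: substitution rate of conserved family members (per unit
    time, spent on the planted species branch).  ``baseline_var``: variance
    scale of the per-branch lognormal baseline.  Divergent relative rates
    are ``1 + Gamma(shape, scale)`` or ``Uniform(1, r_max]``; the paralog
    fate weights are (conservation, subfunctionalization,
    neofunctionalization) and are normalised to sum to 1.
    """

    mean_rate: float = 1.0
    baseline_var: float = 0.2
    divergent: str = "gamma"          # "gamma" | "uniform"
    gamma_shape: float = 2.0
    gamma_scale: float = 0.5
    uniform_rmax: float = 3.0
    fate_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        w = np.asarray(self.fate_weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("fate weights must be nonnegative, not all zero")
        self.fate_weights = tuple(w / w.sum())

    def draw_divergent(self, rng: np.random.Generator) -> float:
        if self.divergent == "gamma":
            return 1.0 + rng.gamma(self.gamma_shape, self.gamma_scale)
        if self.divergent == "uniform":
            return rng.uniform(1.0, self.uniform_rmax)
        raise ValueError(f"unknown divergent-rate distribution {self.divergent!r}")


@dataclass
class RateSchedule:
    """Per-edge conserved/divergent marks and rate lists.

    Edges are keyed by the id of their lower (child) vertex.  Each list
    holds ``(tau, omega)`` pairs in decreasing ``tau``, opened at the
    parent's date and closed at the child's date.
    """

    mark: dict[int, str] = field(default_factory=dict)
    lists: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    finalized: bool = False


def write_schedule(schedule: RateSchedule, path_or_handle) -> None:
    """Dump a rate schedule as TSV (edge id, mark, tau, omega) for audit."""
    own = isinstance(path_or_handle, str)
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("edge\tmark\ttau\tomega\n")
        for edge_id in sorted(schedule.lists):
            mark = schedule.mark[edge_id]
            for tau, omega in schedule.lists[edge_id]:
                fh.write(f"{edge_id}\t{mark}\t{tau:.10g}\t{omega:.10g}\n")
    finally:
        if own:
            fh.close()


def baseline_rates(S: PlantedTree, cfg: RateConfig = RateConfig(),
                   seed: RngLike = None) -> dict[int, float]:
    """Baseline substitution rate per species branch (keyed by lower vertex).

    The log-rate of branch ``uv`` is normal with variance
    ``baseline_var * (tau(u) - tau(v))``; the mean is shifted by minus half
    the variance so that ``E[omega] = omega_parent`` (lognormal mean
    correction).
    """
    rng = _rng(seed)
    rates = {S.root.id: cfg.mean_rate}   # planted branch
    for u in S.preorder(include_planted=False):
        for v in u.children:
            var = cfg.baseline_var * (u.tau - v.tau)
            parent_rate = rates[u.id]
            if var <= 0:
                rates[v.id] = parent_rate
            else:
                mu_log = np.log(parent_rate) - var / 2.0
                rates[v.id] = float(np.exp(rng.normal(mu_log, np.sqrt(var))))
    return rates


def assign_gene_rates(scn: GeneScenario, cfg: RateConfig = RateConfig(),
                      seed: RngLike = None) -> RateSchedule:
    """Walk the dated gene tree and build per-edge rate lists.

    Vertices are processed in descending date order.  Speciation children
    inherit the parent edge's mark; duplications of a conserved edge draw a
    paralog fate; a loss that leaves a single copy in its species branch
    reverts the surviving edge to the conserved state from the loss time
    on; HGT keeps the resident copy unchanged and marks the transferred
    copy divergent.
    """
    rng = _rng(seed)
    T = scn.tree
    sched = RateSchedule()
    root = T.root

    # edges spanning a time point, per species branch (for the loss rule)
    edges_by_branch: dict[int, list[TreeNode]] = {}
    for v in T.preorder(include_planted=False):
        edges_by_branch.setdefault(v.sbranch, []).append(v)

    def open_edge(child: TreeNode, mark: str, tau: float, omega: float) -> None:
        sched.mark[child.id] = mark
        sched.lists[child.id] = [(tau, omega)]

    def append(child: TreeNode, tau: float, omega: float) -> None:
        sched.lists[child.id].append((tau, omega))

    def child_rate(mark: str) -> float:
        return 1.0 if mark == "conserved" else cfg.draw_divergent(rng)

    open_edge(root, "conserved", T.planted_root.tau, 1.0)

    events = [v for v in T.preorder(include_planted=False)
              if v.event in ("speciation", "duplication", "hgt", "loss")]
    events.sort(key=lambda v: (-v.tau, v.id))
    for u in events:
        if u.event == "speciation":
            mark = sched.mark[u.id]
            for v in u.children:
                open_edge(v, mark, u.tau, child_rate(mark))
        elif u.event == "duplication":
            if sched.mark[u.id] == "divergent":
                marks = ("divergent", "divergent")
            else:
                fate = rng.choice(3, p=cfg.fate_weights)
                if fate == 0:      # conservation
                    marks = ("conserved", "conserved")
                elif fate == 1:    # subfunctionalization
                    marks = ("divergent", "divergent")
                else:              # neofunctionalization
                    marks = ("conserved", "divergent") if rng.random() < 0.5 \
                        else ("divergent", "conserved")
            for v, mark in zip(u.children, marks):
                open_edge(v, mark, u.tau, child_rate(mark))
        elif u.event == "hgt":
            mark = sched.mark[u.id]
            last_omega = sched.lists[u.id][-1][1]
            for v in u.children:
                if v.transferred:
                    open_edge(v, "divergent", u.tau, cfg.draw_divergent(rng))
                else:
                    open_edge(v, mark, u.tau, last_omega)
        else:  # loss: last-survivor reversion
            survivors = [e for e in edges_by_branch.get(u.sbranch, ())
                         if e.parent.tau > u.tau > e.tau]
            if len(survivors) == 1:
                e_star = survivors[0]
                sched.mark[e_star.id] = "conserved"
                append(e_star, u.tau, 1.0)

    for v in T.preorder(include_planted=False):
        last_omega = sched.lists[v.id][-1][1]
        append(v, v.tau, last_omega)
    sched.finalized = True
    return sched


def integrate_rate_list(pairs: list[tuple[float, float]]) -> float:
    """Time integral of a piecewise-constant rate list.

    ``sum_i omega_i * (tau_i - tau_{i+1})`` over consecutive pairs; the
    final pair only closes the last segment.
    """
    return sum(w0 * (t0 - t1)
               for (t0, w0), (t1, _) in zip(pairs, pairs[1:]))


def edge_lengths(scn: GeneScenario, schedule: RateSchedule,
                 baseline: dict[int, float]) -> dict[int, float]:
    """Edge lengths from the rate lists; also stored on the tree vertices.

    ``l(e) = omega0_f * sum_i omega_i * (tau_i - tau_{i+1})`` where ``f``
    is the species branch hosting ``e``.
    """
    if not schedule.finalized:
        raise ValueError("rate schedule is not finalized")
    out = {}
    for v in scn.tree.preorder(include_planted=False):
        length = baseline[v.sbranch] * integrate_rate_list(schedule.lists[v.id])
        v.length = length
        out[v.id] = length
    return out


def scenario_distance_matrix(scn: GeneScenario, cfg: RateConfig = RateConfig(),
                             seed: RngLike = None
                             ) -> tuple[PlantedTree, dict[str, str],
                                        DistanceMatrix]:
    """Full pipeline: rates -> edge lengths -> observable tree -> distances."""
    rng = _rng(seed)
    base = baseline_rates(scn.species_tree, cfg, rng)
    sched = assign_gene_rates(scn, cfg, rng)
    edge_lengths(scn, sched, base)
    obs, color = prune_to_observable(scn)
    return obs, color, obs.path_distance_matrix()
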