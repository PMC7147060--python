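"""Leaf-indexed distance matrices and quartet inference.

The quartet topology on four leaves is read off an additive distance via
the four-point condition: the split ``(pq|rs)`` holds iff
``d(p,q) + d(r,s)`` is strictly smaller than both other pairings.  For
additive data the two larger sums coincide; for the star topology all
three sums are equal and no split is called.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["DistanceMatrix", "QuartetCall", "infer_quartet", "is_additive",
           "quartet_calls_vs_outgroups"]


class DistanceMatrix:
    """Symmetric nonnegative matrix with ordered leaf labels."""

    def __init__(self, labels: Sequence[str], data: np.ndarray):
        labels = list(labels)
        data = np.asarray(data, dtype=float)
        if data.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(data, data.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(data) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(data < 0):
            raise ValueError("distances must be nonnegative")
        self.labels = labels
        self.data = data
        self.index = {lab: i for i, lab in enumerate(labels)}
        if len(self.index) != len(labels):
            raise ValueError("duplicate leaf labels")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return self.data[self.index[a], self.index[b]]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index[l] for l in labels]
        return DistanceMatrix(list(labels), self.data[np.ix_(idx, idx)])

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(self.labels, self.data.copy())

    def is_metric(self, tol: float = 1e-9) -> bool:
        """Triangle inequality over all ordered triples."""
        d = self.data
        n = len(d)
        for k in range(n):
            # d[i,j] <= d[i,k] + d[k,j] for all i, j
            if np.any(d > d[:, [k]] + d[[k], :] + tol):
                return False
        return True


@dataclass(frozen=True)
class QuartetCall:
    """Topology call on four leaves.

    ``split`` is a pair of 2-sets of leaf labels, or ``None`` for the star
    (unresolved) topology.
    """

    leaves: tuple[str, str, str, str]
    split: Optional[tuple[frozenset, frozenset]]

    @property
    def is_star(self) -> bool:
        return self.split is None

    def pairs_with(self, a: str, b: str) -> bool:
        """True iff the call is resolved and places ``a`` and ``b`` together."""
        if self.split is None:
            return False
        side = frozenset((a, b))
        return side in self.split


def _call_from_sums(s: np.ndarray, rel_tol: float) -> int:
    """Index (0..2) of the strictly smallest sum, or -1 (star).

    A split is called only when its sum is below both others by more than
    ``rel_tol`` times the largest sum, which realises the strict inequality
    of the four-point criterion with a floating-point margin.
    """
    margin = rel_tol * float(np.max(s))
    order = np.argsort(s, kind="stable")
    if s[order[1]] - s[order[0]] > margin:
        return int(order[0])
    return -1


def infer_quartet(D: DistanceMatrix, p: str, q: str, r: str, s: str,
                  rel_tol: float = 1e-9) -> QuartetCall:
    """Call the quartet topology on ``{p, q, r, s}`` from distances."""
    leaves = (p, q, r, s)
    if len(set(leaves)) != 4:
        raise ValueError("quartet leaves must be pairwise distinct")
    i, j, k, l = (D.index[x] for x in leaves)
    d = D.data
    sums = np.array([d[i, j] + d[k, l],    # (pq|rs)
                     d[i, k] + d[j, l],    # (pr|qs)
                     d[i, l] + d[j, k]])   # (ps|qr)
    splits = [(frozenset((p, q)), frozenset((r, s))),
              (frozenset((p, r)), frozenset((q, s))),
              (frozenset((p, s)), frozenset((q, r)))]
    w = _call_from_sums(sums, rel_tol)
    return QuartetCall(leaves, None if w < 0 else splits[w])


def quartet_calls_vs_outgroups(D: DistanceMatrix, x: str, y1: str, y2: str,
                               outgroups: Sequence[str],
                               rel_tol: float = 1e-9) -> np.ndarray:
    """Vectorised quartet calls on ``(x, y1, y2, z)`` for many ``z``.

    Returns an int array over ``outgroups``: 0 for ``(x y1 | y2 z)``,
    1 for ``(x y2 | y1 z)``, 2 for ``(x z | y1 y2)``, -1 for the star.
    """
    d = D.data
    ix, i1, i2 = D.index[x], D.index[y1], D.index[y2]
    iz = np.fromiter((D.index[z] for z in outgroups), dtype=int,
                     count=len(outgroups))
    s0 = d[ix, i1] + d[i2, iz]
    s1 = d[ix, i2] + d[i1, iz]
    s2 = d[ix, iz] + d[i1, i2]
    sums = np.stack([s0, s1, s2])               # (3, k)
    margin = rel_tol * sums.max(axis=0)
    part = np.sort(sums, axis=0)
    winner = np.argmin(sums, axis=0)
    resolved = (part[1] - part[0]) > margin
    return np.where(resolved, winner, -1)


def is_additive(D: DistanceMatrix, tol: float = 1e-9) -> bool:
    """Four-point condition on every 4-subset of leaves.

    A matrix is additive iff, for every quartet, the largest two of the
    three pair sums agree (within ``tol``, scaled by the magnitude of the
    largest sum for values above 1).
    """
    d = D.data
    n = len(d)
    if n < 4:
        return True
    quads = np.array(list(itertools.combinations(range(n), 4)))
    i, j, k, l = quads.T
    sums = np.stack([d[i, j] + d[k, l],
                     d[i, k] + d[j, l],
                     d[i, l] + d[j, k]])
    sums.sort(axis=0)
    scale = np.maximum(1.0, sums[2])
    return bool(np.all(sums[2] - sums[1] <= tol * scale))
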