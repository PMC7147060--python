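"""Measurement-noise models for additive distance matrices.

Multiplicative noise rescales one entry at a time by a Normal(1, s)
factor and keeps only proposals that preserve the triangle inequality
against the current matrix (rejection repair), so the output is metric
but in general no longer additive.  Convex-combination noise mixes the
matrix with an additive matrix from an independently simulated tree,
producing a systematically biased metric.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .distances import DistanceMatrix
from .species import simulate_dated_species_tree

__all__ = ["perturb_multiplicative", "perturb_convex"]

RngLike = Union[int, np.random.Generator, None]

_MAX_TRIES_PER_SLOT = 100_000


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def perturb_multiplicative(D: DistanceMatrix, s: float,
                           seed: RngLike = None) -> DistanceMatrix:
    """Sequential multiplicative noise with triangle-inequality rejection.

    Repeatedly picks a random unordered leaf pair (with replacement),
    proposes ``d' = eps * d(x, y)`` with ``eps ~ Normal(1, s)``, and
    accepts iff ``d' > 0`` and the triangle inequality still holds against
    the current (already partially perturbed) matrix; runs until
    ``C(n, 2)`` proposals have been accepted.
    """
    if s < 0:
        raise ValueError("noise level s must be nonnegative")
    rng = _rng(seed)
    d = D.data.copy()
    n = len(D)
    if s == 0 or n < 2:
        return DistanceMatrix(D.labels, d)
    n_slots = n * (n - 1) // 2
    accepted = 0
    tries = 0
    mask = np.ones(n, dtype=bool)
    while accepted < n_slots:
        tries += 1
        if tries > _MAX_TRIES_PER_SLOT:
            raise RuntimeError(
                "noise rejection sampling failed to find an acceptable "
                "perturbation (retry cap reached)")
        i = rng.integers(n)
        j = rng.integers(n - 1)
        if j >= i:
            j += 1
        eps = rng.normal(1.0, s)
        dp = eps * d[i, j]
        if dp <= 0:
            continue
        mask[:] = True
        mask[[i, j]] = False
        di, dj = d[i, mask], d[j, mask]
        if np.any(dp > di + dj) or np.any(di > dp + dj) or np.any(dj > dp + di):
            continue
        d[i, j] = d[j, i] = dp
        accepted += 1
        tries = 0
    return DistanceMatrix(D.labels, d)


def perturb_convex(D: DistanceMatrix, alpha: float, seed: RngLike = None,
                   alternative: Optional[DistanceMatrix] = None
                   ) -> DistanceMatrix:
    """Systematically biased noise ``(1 - alpha) * D + alpha * D'``.

    ``D'`` is an additive matrix on the same leaves; by default it is the
    (ultrametric, hence additive) leaf-distance matrix of an independently
    simulated dated tree with the same number of leaves, matched to ``D``'s
    leaves in order.  A convex combination of metrics is a metric, but is
    generally not additive.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alternative is None:
        rng = _rng(seed)
        alt_tree = simulate_dated_species_tree(len(D), rng)
        alt = alt_tree.path_distance_matrix()
        order = sorted(alt.labels)
        data = alt.submatrix(order).data
        alternative = DistanceMatrix(D.labels, data)
    elif alternative.labels != D.labels:
        raise ValueError("alternative matrix must share the leaf order")
    mixed = (1.0 - alpha) * D.data + alpha * alternative.data
    return DistanceMatrix(D.labels, mixed)
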