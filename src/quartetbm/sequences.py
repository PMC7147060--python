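"""Sequence simulation, distance estimation, and quartet mapping.

Gap-free sequences evolve along the observable gene tree under a
continuous-time Markov substitution model (K80 for nucleotides, WAG for
amino acids), with the expected number of substitutions per site on an
edge equal to its length times an optional rate scale.  Distances are
re-estimated from the simulated alignments (Jukes-Cantor transform for
DNA, BLOSUM-score based distance for proteins).  Quartet mapping calls a
quartet topology directly from the site patterns of a four-sequence
alignment, without estimating distances at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.linalg import expm

from ._wag import WAG_ALPHABET, WAG_EXCHANGE, WAG_FREQS
from .distances import DistanceMatrix
from .trees import PlantedTree

__all__ = ["Alignment", "simulate_sequences", "jc_distance",
           "protein_distance", "alignment_distance_matrix",
           "site_category_counts", "qm_support", "qm_call"]

DNA = "ACGT"
RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Alignment:
    """Equal-length, gap-free sequences with ordered labels."""

    labels: list[str]
    seqs: list[str]
    alphabet: str = DNA

    def __post_init__(self):
        if len(self.labels) != len(self.seqs):
            raise ValueError("labels and sequences differ in number")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("alignment sequences must have equal length")
        valid = set(self.alphabet)
        for s in self.seqs:
            bad = set(s) - valid
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __getitem__(self, label: str) -> str:
        return self.seqs[self.labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "Alignment":
        return Alignment(list(labels), [self[l] for l in labels],
                         self.alphabet)

    def to_fasta(self, path_or_handle) -> None:
        own = isinstance(path_or_handle, str)
        fh = open(path_or_handle, "w") if own else path_or_handle
        try:
            for lab, seq in zip(self.labels, self.seqs):
                fh.write(f">{lab}\n{seq}\n")
        finally:
            if own:
                fh.close()

    @classmethod
    def from_fasta(cls, path_or_handle, alphabet: str = DNA) -> "Alignment":
        own = isinstance(path_or_handle, str)
        fh = open(path_or_handle) if own else path_or_handle
        try:
            labels, seqs, cur = [], [], []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    labels.append(line[1:].split()[0])
                    seqs.append(cur := [])
                elif line:
                    cur.append(line)
            return cls(labels, ["".join(p) for p in seqs], alphabet)
        finally:
            if own:
                fh.close()


# ---------------------------------------------------------------------------
# substitution models

def _normalize_q(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(Q)))
    return Q / scale


def k80_model(kappa: float = 1.0) -> tuple[np.ndarray, np.ndarray, str]:
    """Kimura 2-parameter rate matrix; ``kappa`` is the transition /
    transversion *rate* ratio (expected event-count ratio ``kappa / 2``)."""
    pi = np.full(4, 0.25)
    Q = np.ones((4, 4))
    # alphabet ACGT: transitions A<->G (0,2) and C<->T (1,3)
    Q[0, 2] = Q[2, 0] = Q[1, 3] = Q[3, 1] = kappa
    Q = Q * pi[None, :]
    return _normalize_q(Q, pi), pi, DNA


def wag_model() -> tuple[np.ndarray, np.ndarray, str]:
    pi = WAG_FREQS.copy()
    Q = WAG_EXCHANGE * pi[None, :]
    return _normalize_q(Q, pi), pi, WAG_ALPHABET


def kappa_from_titv(ratio: float) -> float:
    """Rate-ratio kappa giving a desired transition:transversion event
    count ratio (each state has one transition and two transversion
    partners, so the event ratio is ``kappa / 2``)."""
    return 2.0 * ratio


def simulate_sequences(tree: PlantedTree, root_length: int,
                       model: str = "K80", kappa: float = 1.0,
                       rate_scale: float = 1.0,
                       seed: RngLike = None) -> Alignment:
    """Evolve i.i.d. sites along the tree; leaves become the alignment.

    The root sequence is drawn from the model's stationary distribution;
    each edge applies ``P = expm(Q * rate_scale * l(e))``.
    """
    if root_length < 1:
        raise ValueError("root_length must be at least 1")
    if model.upper() == "K80":
        Q, pi, alphabet = k80_model(kappa)
    elif model.upper() == "WAG":
        Q, pi, alphabet = wag_model()
    else:
        raise ValueError(f"unknown substitution model {model!r}")
    rng = _rng(seed)
    n_states = len(pi)

    seqs: dict[int, np.ndarray] = {}
    root = tree.root
    seqs[root.id] = rng.choice(n_states, size=root_length, p=pi)
    labels, out = [], []
    for v in tree.preorder(include_planted=False):
        if v is not root:
            if v.length is None:
                raise ValueError("edge lengths must be set")
            P = expm(Q * (rate_scale * v.length))
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            parent_seq = seqs[v.parent.id]
            child = np.empty_like(parent_seq)
            for state in range(n_states):
                idx = np.nonzero(parent_seq == state)[0]
                if idx.size:
                    child[idx] = rng.choice(n_states, size=idx.size,
                                            p=P[state])
            seqs[v.id] = child
        if v.is_leaf:
            labels.append(v.label)
            out.append("".join(alphabet[i] for i in seqs[v.id]))
    return Alignment(labels, out, alphabet)


# ---------------------------------------------------------------------------
# distance estimation

def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor corrected distance ``-(3/4) ln(1 - 4p/3)``.

    Saturated pairs (``p >= 3/4``) give ``inf``; see
    :func:`alignment_distance_matrix` for the finite-cap policy.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    n = len(seq_a)
    if n == 0:
        raise ValueError("empty sequences")
    p = sum(a != b for a, b in zip(seq_a, seq_b)) / n
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def protein_distance(seq_a: str, seq_b: str, matrix=None) -> float:
    """Score-based protein distance ``1 - S(a,b) / max(S(a,a), S(b,b))``.

    ``S`` is the summed substitution score (BLOSUM62 by default); the
    distance is 0 for identical sequences and increases monotonically
    with divergence.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    m = matrix if matrix is not None else _blosum62()
    try:
        s_ab = sum(m[a, b] for a, b in zip(seq_a, seq_b))
        s_aa = sum(m[a, a] for a in seq_a)
        s_bb = sum(m[b, b] for b in seq_b)
    except (KeyError, IndexError) as exc:
        raise ValueError(f"unknown residue: {exc}") from None
    return 1.0 - s_ab / max(s_aa, s_bb)


def alignment_distance_matrix(aln: Alignment,
                              method: str = "jc") -> DistanceMatrix:
    """Pairwise corrected distances for a whole alignment.

    Saturated Jukes-Cantor pairs are capped at twice the largest finite
    estimate in the matrix so that downstream quartet sums and NJ remain
    computable.
    """
    n = len(aln.labels)
    mat = np.zeros((n, n))
    fn = jc_distance if method == "jc" else protein_distance
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(aln.seqs[i], aln.seqs[j])
    finite = mat[np.isfinite(mat)]
    cap = 2.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
    mat[~np.isfinite(mat)] = cap
    return DistanceMatrix(aln.labels, mat)


# ---------------------------------------------------------------------------
# quartet mapping (statistical geometry)

def site_category_counts(aln4: Alignment) -> dict[str, int]:
    """Counts of the 15 identity-pattern categories of a 4-row alignment.

    Categories are keyed by their canonical pattern string (``aabb``,
    ``abac``, ...): the first occurrence of each character is renamed
    ``a``, ``b``, ... in order of appearance.
    """
    if len(aln4.labels) != 4:
        raise ValueError("quartet mapping needs exactly 4 sequences")
    counts: dict[str, int] = {}
    for col in zip(*aln4.seqs):
        names: dict[str, str] = {}
        key = "".join(names.setdefault(ch, "abcd"[len(names)]) for ch in col)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _canon(pattern: str) -> str:
    """Rename characters to first-occurrence order (equality structure)."""
    names: dict[str, str] = {}
    return "".join(names.setdefault(ch, "abcd"[len(names)]) for ch in pattern)


# support patterns per split, canonicalised to first-occurrence naming
_SUPPORT_PATTERNS = tuple(
    tuple(_canon(p) for p in group) for group in (
        ("aabb", "aabc", "bcaa"),   # S(x y' | y'' z)
        ("abab", "abac", "baca"),   # S(x y'' | y' z)
        ("abba", "abca", "baac"),   # S(x z | y' y'')
    ))


def qm_support(aln4: Alignment, weighted: bool = False,
               char_metric: Optional[Callable[[str, str], float]] = None
               ) -> np.ndarray:
    """Normalised quartet-mapping support scores for a 4-row alignment.

    Rows are interpreted in order ``x, y', y'', z``.  Unweighted scores
    count full-support patterns once and partial-support patterns (one
    extra character state) with weight 1/2.  The weighted variant scores
    every column by its isolation index under a character metric
    ``D``: ``2 beta(split) = D* - (sum of the split's two distances)``
    with ``D*`` the largest of the three distance sums; with the trivial
    metric ``D(a, b) = 1 - delta(a, b)`` it reduces to the unweighted
    scores.  Returns three scores summing to 1, or zeros when no column
    is informative.
    """
    if len(aln4.labels) != 4:
        raise ValueError("quartet mapping needs exactly 4 sequences")
    if not weighted:
        counts = site_category_counts(aln4)
        raw = np.array([
            counts.get(full, 0) + 0.5 * (counts.get(h1, 0) + counts.get(h2, 0))
            for full, h1, h2 in _SUPPORT_PATTERNS])
    else:
        metric = char_metric if char_metric is not None else \
            (lambda a, b: 0.0 if a == b else 1.0)
        raw = np.zeros(3)
        for col in zip(*aln4.seqs):
            x, y1, y2, z = col
            sums = np.array([metric(x, y1) + metric(y2, z),
                             metric(x, y2) + metric(y1, z),
                             metric(x, z) + metric(y1, y2)])
            raw += (sums.max() - sums) / 2.0
    total = raw.sum()
    if total <= 0:
        return np.zeros(3)
    return raw / total


def qm_call(scores: np.ndarray, tol: float = 0.0) -> int:
    """Quartet code from support scores: the strict maximum wins.

    Returns 0 for ``(x y'|y'' z)``, 1 for ``(x y''|y' z)``, 2 for
    ``(x z|y' y'')``, or -1 (star) when all scores vanish or the maximum
    is tied (within ``tol``).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.sum() <= 0:
        return -1
    order = np.argsort(scores)
    if scores[order[2]] - scores[order[1]] <= tol:
        return -1
    return int(order[2])


def qm_quartet_codes(aln: Alignment, weighted: bool = False,
                     char_metric=None) -> Callable:
    """Adapter for :func:`quartetbm.inference.quartet_best_matches`.

    Returns a callable mapping ``(x, y1, y2, Z)`` to an int array of
    quartet codes obtained by quartet mapping on the stored alignment.
    """
    def codes(x: str, y1: str, y2: str, zs: Sequence[str]) -> np.ndarray:
        out = np.empty(len(zs), dtype=int)
        for k, z in enumerate(zs):
            sub = aln.subset([x, y1, y2, z])
            out[k] = qm_call(qm_support(sub, weighted, char_metric))
        return out
    return codes
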