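"""Unified distance: delay-damped random-walk closeness between proteins.

For the augmented transition matrix P and delay parameter c in (0, 1)
the unified distance matrix is the damped sum over all walk lengths

    R = sum_{l>=1} c (1-c)^l P^l,

which weights short walks geometrically more than long ones.  Because
the spectral radius of (1-c)P is at most 1-c < 1 the series converges
and has the closed form

    R = c (1-c) P (I - (1-c) P)^{-1},

evaluated here by solving a linear system rather than inverting.  Walks
are summed over the full augmented graph, so dummy vertices act as
intermediate states: two proteins sharing a GO slim gain an extra
two-step path through its dummy vertex, which enlarges their closeness.
Only the protein-by-protein block is returned; entries are bounded by
sum_l c(1-c)^l = 1-c.

R is asymmetric in general (row degrees differ); consumers use the
symmetrised value r(u, v) = (R[u,v] + R[v,u]) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from coan.augmented_network import TransitionMatrix
from coan.errors import NumericError, UsageError

__all__ = ["DistanceMatrix", "unified_distance", "unified_distance_series"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Protein-by-protein closeness matrix (larger = closer)."""

    values: np.ndarray
    c: float
    protein_order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {p: i for i, p in enumerate(self.protein_order)})

    def index_of(self, protein: str) -> int:
        try:
            return self._index[protein]
        except KeyError:
            raise KeyError(f"protein not indexed in distance matrix: {protein!r}") from None

    def sym(self, u: str, v: str) -> float:
        """Symmetrised closeness r(u, v) = (R[u,v] + R[v,u]) / 2."""
        i, j = self.index_of(u), self.index_of(v)
        return 0.5 * (self.values[i, j] + self.values[j, i])

    def dump_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.protein_order) + "\n")
            for label, row in zip(self.protein_order, self.values):
                fh.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def _check_c(c: float) -> None:
    if not (0.0 < c < 1.0):
        raise UsageError(f"delay parameter c must lie in (0, 1), got {c}")


def unified_distance(P: TransitionMatrix, c: float = 0.1) -> DistanceMatrix:
    """Closed-form unified distance, restricted to the protein block."""
    _check_c(c)
    A = P.toarray()
    n = A.shape[0]
    M = np.eye(n) - (1.0 - c) * A
    # R = c(1-c) P M^{-1}; solve M^T X = P^T so X^T = P M^{-1}
    try:
        X = np.linalg.solve(M.T, A.T)
    except np.linalg.LinAlgError as exc:  # cannot occur for substochastic P
        raise NumericError(f"singular random-walk system: {exc}") from exc
    R = c * (1.0 - c) * X.T
    k = P.n_proteins
    return DistanceMatrix(np.ascontiguousarray(R[:k, :k]), c, P.vertex_order[:k])


def unified_distance_series(P: TransitionMatrix, c: float, L: int) -> DistanceMatrix:
    """Truncated series sum_{l=1..L} c(1-c)^l P^l (brute-force oracle).

    Slower than the closed form and exact only in the limit; it exists to
    cross-check :func:`unified_distance` and for pedagogy.
    """
    _check_c(c)
    if L < 1:
        raise UsageError(f"series length L must be >= 1, got {L}")
    A = P.toarray()
    n = A.shape[0]
    acc = np.zeros((n, n))
    power = np.eye(n)
    w = c
    for _ in range(L):
        power = power @ A
        w *= 1.0 - c
        acc += w * power
    k = P.n_proteins
    return DistanceMatrix(np.ascontiguousarray(acc[:k, :k]), c, P.vertex_order[:k])
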