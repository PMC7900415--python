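"""Similarity network fusion (SNF) of two similarity views.

Each entity class (diseases, miRNAs) has two complementary similarity
views — a knowledge-based one (semantic / functional) and the GIP kernel
computed from the association matrix.  SNF merges them by cross
diffusion: each view's full normalized kernel P is repeatedly propagated
through the *other* view's sparse K-nearest-neighbour kernel S,

    P1 <- S1 . P2 . S1',    P2 <- S2 . P1 . S2',

so reliable local structure in one view spreads global structure from
the other.  After T steps the fused similarity is the average of the
two diffused kernels.

The full kernel normalization puts half the probability mass on the
diagonal (P(i,i) = 1/2, off-diagonal row mass 1/2), which stabilizes
the diffusion; the KNN kernel keeps only each entity's K strongest
neighbours, row-normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import SimilarityMatrix


@dataclass
class SNFConfig:
    """Knobs of the fusion: neighbourhood size K, iteration count T.

    ``n_neighbors=None`` resolves to min(20, n-1) at fusion time.
    ``update_schedule`` is "simultaneous" (both diffused kernels computed
    from the previous pair — the standard cross-diffusion reading) or
    "sequential" (the second update sees the already-updated first
    kernel).  ``symmetrize_each_step`` re-symmetrizes and re-normalizes
    the kernels after every diffusion step, which keeps them
    row-stochastic; disable for the bare iteration.
    """

    n_neighbors: int | None = None
    n_iterations: int = 20
    symmetrize_each_step: bool = True
    update_schedule: str = "simultaneous"

    def resolved_k(self, n: int) -> int:
        k = min(20, n - 1) if self.n_neighbors is None else self.n_neighbors
        if not (1 <= k <= n - 1):
            raise ValueError(f"n_neighbors must lie in [1, {n - 1}], got {k}")
        return k


def normalize_weights(W: np.ndarray | SimilarityMatrix) -> np.ndarray:
    """Full-graph normalized kernel: P(i,i) = 1/2, off-diagonal row mass 1/2.

    P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k)) for j != i.  A row with
    zero off-diagonal mass gets the uniform distribution over its
    off-diagonal slots (with a warning) so the operator stays total.
    """
    W = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    zero_rows = row_sums == 0.0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} row(s) with zero off-diagonal similarity; "
            "using uniform neighbour weights",
            stacklevel=2,
        )
        off[zero_rows, :] = 1.0
        np.fill_diagonal(off, 0.0)
        row_sums = off.sum(axis=1)
    P = off / (2.0 * row_sums[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def knn_kernel(W: np.ndarray | SimilarityMatrix, K: int) -> np.ndarray:
    """Sparse local kernel: each row keeps its K strongest neighbours.

    Self-similarity is excluded; the kept weights are renormalized to
    sum to 1 per row (zero diagonal).  Ties at the K-th neighbour break
    by column index.  A row whose K neighbours all have zero weight gets
    the uniform distribution over those slots, with a warning.
    """
    W = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (1 <= K <= n - 1):
        raise ValueError(f"K must lie in [1, {n - 1}], got {K}")
    off = W.copy()
    np.fill_diagonal(off, -np.inf)  # never pick self
    # stable top-K by (weight desc, index asc)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), -off), axis=1)
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), K)
    cols = order[:, :K].ravel()
    S[rows, cols] = W[rows, cols]
    row_sums = S.sum(axis=1)
    zero_rows = row_sums == 0.0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} row(s) with all-zero neighbour weights; "
            "using uniform weights over the K selected neighbours",
            stacklevel=2,
        )
        for i in np.flatnonzero(zero_rows):
            S[i, order[i, :K]] = 1.0
        row_sums = S.sum(axis=1)
    return S / row_sums[:, None]


def _stabilize(P: np.ndarray) -> np.ndarray:
    """Symmetrize and re-apply the half-diagonal row normalization."""
    P = (P + P.T) / 2.0
    return normalize_weights(P)


def snf_fuse(
    W1: SimilarityMatrix, W2: SimilarityMatrix, config: SNFConfig | None = None
) -> SimilarityMatrix:
    """Fuse two similarity views of the same entities by cross diffusion.

    With ``n_iterations=0`` this reduces exactly to the (symmetrized)
    average of the two normalized kernels.  The output diagonal is left
    as produced by the diffusion (about 1/2 plus diffusion mass): the
    fused matrix feeds the inductive completion as a feature matrix,
    whose factors absorb its absolute scale.
    """
    config = config or SNFConfig()
    if W1.ids != W2.ids:
        raise ValueError("similarity views have mismatched entity ids")
    n = W1.n
    K = config.resolved_k(n)
    P1 = normalize_weights(W1.values)
    P2 = normalize_weights(W2.values)
    S1 = knn_kernel(W1.values, K)
    S2 = knn_kernel(W2.values, K)
    for _ in range(config.n_iterations):
        if config.update_schedule == "simultaneous":
            P1, P2 = S1 @ P2 @ S1.T, S2 @ P1 @ S2.T
        elif config.update_schedule == "sequential":
            P1 = S1 @ P2 @ S1.T
            P2 = S2 @ P1 @ S2.T
        else:
            raise ValueError(
                f"unknown update_schedule: {config.update_schedule!r}"
            )
        if config.symmetrize_each_step:
            P1 = _stabilize(P1)
            P2 = _stabilize(P2)
    fused = (P1 + P2) / 2.0
    fused = (fused + fused.T) / 2.0
    fused[fused < 0] = 0.0  # guard against tiny negative round-off
    return SimilarityMatrix(fused, list(W1.ids), view_name="fused")
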