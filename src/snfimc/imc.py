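"""Nonnegative inductive matrix completion (IMC) by multiplicative updates.

The association matrix A (nd x nm) is completed through two feature
matrices: the fused disease similarity Sd (nd x nd) and the fused miRNA
similarity Sm (nm x nm).  The model seeks nonnegative low-rank factors
U (nd x r) and V (nm x r) minimizing the regularized Frobenius objective

    Phi(U, V) = 1/2 ||A - Sd U V' Sm'||_F^2
                + lambda1/2 ||U||_F^2 + lambda2/2 ||V||_F^2,
    U >= 0, V >= 0.

Minimization alternates NMF-style multiplicative updates, which preserve
nonnegativity and drive Phi monotonically downward because every matrix
entering the update ratios is nonnegative:

    V <- V * (Sm' A' Sd U) / (Sm' Sm V U' Sd' Sd U + lambda2 V)
    U <- U * (Sd' A  Sm V) / (Sd' Sd U V' Sm' Sm V + lambda1 U)

The completed score S(di, mj) = Sd(i) U V' Sm(j)' is defined for any
entity with a feature vector, so a disease with no training rows can
still be scored from its similarity profile alone (the "inductive" part).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationMatrix, ScoreMatrix, SimilarityMatrix

#: additive guard on update denominators against 0/0
EPS = 1e-12


@dataclass
class IMCConfig:
    """Solver knobs: factor rank, regularization, stopping rule, seed.

    ``lambda_mode="fixed"`` uses lambda1/lambda2 as given; "scaled" sets
    both to 1/||A||_F at fit time.  The stopping rule is relative change
    of the objective below ``tol``, capped at ``max_iter`` iterations.
    """

    rank: int = 50
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda_mode: str = "fixed"
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be positive, got {self.rank}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.lambda_mode not in ("fixed", "scaled"):
            raise ValueError(f"unknown lambda_mode: {self.lambda_mode!r}")


@dataclass
class IMCFactors:
    """Fitted nonnegative factors with the per-iteration objective trace."""

    U: np.ndarray
    V: np.ndarray
    objective_trace: list[float]
    n_iterations_run: int
    converged: bool = False


def _values(M: np.ndarray | SimilarityMatrix | AssociationMatrix) -> np.ndarray:
    if isinstance(M, (SimilarityMatrix, AssociationMatrix)):
        return M.values
    return np.asarray(M, dtype=float)


def _check_shapes(A: np.ndarray, Sd: np.ndarray, Sm: np.ndarray,
                  U: np.ndarray, V: np.ndarray) -> None:
    nd, nm = A.shape
    if Sd.shape != (nd, nd) or Sm.shape != (nm, nm):
        raise ValueError(
            f"feature matrices {Sd.shape}, {Sm.shape} do not conform to A {A.shape}"
        )
    if U.shape[0] != nd or V.shape[0] != nm or U.shape[1] != V.shape[1]:
        raise ValueError(
            f"factor shapes {U.shape}, {V.shape} do not conform to A {A.shape}"
        )


def imc_objective(A, Sd, Sm, U, V, lambda1: float, lambda2: float) -> float:
    """The regularized Frobenius objective Phi(U, V)."""
    A, Sd, Sm = _values(A), _values(Sd), _values(Sm)
    _check_shapes(A, Sd, Sm, U, V)
    resid = A - Sd @ U @ V.T @ Sm.T
    return 0.5 * (
        float(np.sum(resid * resid))
        + lambda1 * float(np.sum(U * U))
        + lambda2 * float(np.sum(V * V))
    )


def update_V(A, Sd, Sm, U, V, lambda2: float) -> np.ndarray:
    """One multiplicative step on V (U held fixed); never increases Phi."""
    A, Sd, Sm = _values(A), _values(Sd), _values(Sm)
    _check_shapes(A, Sd, Sm, U, V)
    SdU = Sd @ U
    num = Sm.T @ (A.T @ SdU)
    den = (Sm.T @ Sm) @ V @ (SdU.T @ SdU) + lambda2 * V + EPS
    return V * (num / den)


def update_U(A, Sd, Sm, U, V, lambda1: float) -> np.ndarray:
    """One multiplicative step on U (V held fixed); never increases Phi."""
    A, Sd, Sm = _values(A), _values(Sd), _values(Sm)
    _check_shapes(A, Sd, Sm, U, V)
    SmV = Sm @ V
    num = Sd.T @ (A @ SmV)
    den = (Sd.T @ Sd) @ U @ (SmV.T @ SmV) + lambda1 * U + EPS
    return U * (num / den)


def fit_imc(A, Sd, Sm, config: IMCConfig | None = None) -> IMCFactors:
    """Alternate the V and U updates until the objective stabilizes.

    Factors are initialized uniform-random in (0, 1) from ``config.seed``;
    the run stops when the relative objective change drops below
    ``config.tol`` or after ``config.max_iter`` iterations.  The full
    objective trace (including the initial value) is retained.
    """
    config = config or IMCConfig()
    Av, Sdv, Smv = _values(A), _values(Sd), _values(Sm)
    nd, nm = Av.shape
    if config.rank > min(nd, nm):
        raise ValueError(
            f"rank {config.rank} exceeds min(nd, nm) = {min(nd, nm)}"
        )
    l1, l2 = config.lambda1, config.lambda2
    if config.lambda_mode == "scaled":
        norm_a = float(np.linalg.norm(Av))
        if norm_a == 0.0:
            raise ValueError("scaled lambda_mode requires a nonzero association matrix")
        l1 = l2 = 1.0 / norm_a
    rng = np.random.default_rng(config.seed)
    U = rng.uniform(size=(nd, config.rank))
    V = rng.uniform(size=(nm, config.rank))
    trace = [imc_objective(Av, Sdv, Smv, U, V, l1, l2)]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        V = update_V(Av, Sdv, Smv, U, V, l2)
        U = update_U(Av, Sdv, Smv, U, V, l1)
        phi = imc_objective(Av, Sdv, Smv, U, V, l1, l2)
        if not np.isfinite(phi):
            raise FloatingPointError(
                f"objective became non-finite at iteration {n_iter}"
            )
        prev = trace[-1]
        trace.append(phi)
        if abs(prev - phi) / max(prev, EPS) < config.tol:
            converged = True
            break
    return IMCFactors(U, V, trace, n_iter, converged)


def predict_scores(Sd, Sm, factors: IMCFactors,
                   disease_ids: list[str] | None = None,
                   mirna_ids: list[str] | None = None) -> ScoreMatrix:
    """Completed score matrix S = Sd U V' Sm' over all pairs."""
    Sdv, Smv = _values(Sd), _values(Sm)
    values = Sdv @ factors.U @ factors.V.T @ Smv.T
    if disease_ids is None:
        disease_ids = list(Sd.ids) if isinstance(Sd, SimilarityMatrix) else [
            f"d{i}" for i in range(values.shape[0])
        ]
    if mirna_ids is None:
        mirna_ids = list(Sm.ids) if isinstance(Sm, SimilarityMatrix) else [
            f"m{j}" for j in range(values.shape[1])
        ]
    return ScoreMatrix(values, disease_ids, mirna_ids)


def predict_novel_disease(sd_new: np.ndarray, Sm, factors: IMCFactors) -> np.ndarray:
    """Scores for a disease outside the training rows, from its feature vector.

    ``sd_new`` is the new disease's similarity profile against the nd
    training diseases (an indicator vector of training disease i
    reproduces row i of :func:`predict_scores`).
    """
    sd_new = np.asarray(sd_new, dtype=float).ravel()
    Smv = _values(Sm)
    if sd_new.shape[0] != factors.U.shape[0]:
        raise ValueError(
            f"feature vector length {sd_new.shape[0]} does not match "
            f"{factors.U.shape[0]} training diseases"
        )
    return sd_new @ factors.U @ factors.V.T @ Smv.T
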