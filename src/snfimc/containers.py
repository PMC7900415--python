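"""Core in-memory containers shared across the pipeline.

All stages of the pipeline exchange three matrix containers — the binary
disease x miRNA association matrix, square symmetric similarity matrices
over one entity class, and the real-valued prediction score matrix — plus
the disease term DAG defined in :mod:`snfimc.dag`.  Each container
validates its own invariants on construction so that indexing mistakes
(misaligned ids, asymmetric similarities, non-binary associations) fail
early rather than silently corrupting downstream results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: absolute tolerance under which a similarity matrix counts as symmetric
SYMMETRY_ATOL = 1e-10


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class AssociationMatrix:
    """Binary adjacency matrix A of verified disease-miRNA associations.

    Rows are diseases, columns are miRNAs; ``values[i, j] == 1`` iff
    disease ``disease_ids[i]`` has a verified association with miRNA
    ``mirna_ids[j]``.
    """

    values: np.ndarray
    disease_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.disease_ids = list(self.disease_ids)
        self.mirna_ids = list(self.mirna_ids)
        if self.values.ndim != 2:
            raise ValueError("association values must be a 2-D matrix")
        if self.values.shape != (len(self.disease_ids), len(self.mirna_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.disease_ids)} diseases x {len(self.mirna_ids)} miRNAs"
            )
        _check_unique(self.disease_ids, "disease")
        _check_unique(self.mirna_ids, "miRNA")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return self.values.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[1]

    @property
    def density(self) -> float:
        return float(self.values.mean())

    def positive_pairs(self) -> np.ndarray:
        """Indices (i, j) of all verified associations, row-major order."""
        return np.argwhere(self.values == 1.0)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.disease_ids), list(self.mirna_ids)
        )

    def masked(self, pairs: np.ndarray) -> "AssociationMatrix":
        """A copy with the given (i, j) entries set to 0 (held-out positives)."""
        out = self.values.copy()
        pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
        out[pairs[:, 0], pairs[:, 1]] = 0.0
        return AssociationMatrix(out, list(self.disease_ids), list(self.mirna_ids))


@dataclass
class SimilarityMatrix:
    """Square symmetric nonnegative similarity over one entity class."""

    values: np.ndarray
    ids: list[str]
    view_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match {n} ids"
            )
        _check_unique(self.ids, "entity")
        if (self.values < 0).any():
            raise ValueError("similarity matrix entries must be nonnegative")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > SYMMETRY_ATOL:
            raise ValueError(f"similarity matrix asymmetric (max deviation {asym:g})")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reordered(self, ids: list[str]) -> "SimilarityMatrix":
        """Permute rows/columns to a new id ordering (ids must be a subset)."""
        missing = [i for i in ids if i not in set(self.ids)]
        if missing:
            raise KeyError(f"ids absent from similarity matrix: {missing}")
        pos = {e: k for k, e in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], list(ids), self.view_name)


@dataclass
class ScoreMatrix:
    """Predicted association scores, aligned with an AssociationMatrix."""

    values: np.ndarray
    disease_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.disease_ids = list(self.disease_ids)
        self.mirna_ids = list(self.mirna_ids)
        if self.values.shape != (len(self.disease_ids), len(self.mirna_ids)):
            raise ValueError(
                f"score matrix shape {self.values.shape} does not match id lists"
            )
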