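"""Synthetic datasets with the structure the pipeline assumes.

A dataset consists of a planted low-rank nonnegative association
structure plus the two auxiliary inputs a real study would bring:

* nonnegative factors U*, V* (gamma-distributed) define latent scores
  L = U* V*' scaled to [0, 1]; associations are Bernoulli draws with
  probability proportional to L, calibrated to the requested density;
* the miRNA functional similarity is the cosine similarity of the V*
  rows, corrupted by a symmetric perturbation of the given magnitude;
* the disease term DAG places diseases with similar U* rows under
  shared subtrees of a random layered scaffold, so the semantic
  similarity echoes the planted disease geometry.

Because every artifact is derived from the same planted factors, the
full pipeline should recover the held-out associations well above
chance — the core parameter-recovery check — while a degree-preserving
shuffle of the association matrix destroys the signal and drops the
cross-validated AUC to chance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics.pairwise import cosine_similarity

from . import io as sio
from .containers import AssociationMatrix, SimilarityMatrix
from .dag import DiseaseDAG


@dataclass
class SyntheticDataset:
    """A complete generated study: associations, similarities, DAG, truth."""

    assoc: AssociationMatrix
    mirna_functional: SimilarityMatrix
    disease_dag: DiseaseDAG
    truth: dict[str, Any]  # planted factors "U", "V" and latent scores "latent"
    seed: int


def generate_dag(n_terms: int, n_layers: int, seed: int) -> DiseaseDAG:
    """Random layered DAG: one root, each non-root term has 1-2 parents
    drawn uniformly from the layer above."""
    if n_layers < 1:
        raise ValueError("n_layers must be at least 1")
    if n_terms < n_layers:
        raise ValueError("need at least one term per layer")
    if n_layers == 1 and n_terms != 1:
        raise ValueError("a single-layer DAG can only hold the root term")
    rng = np.random.default_rng(seed)
    terms = [f"t{i:04d}" for i in range(n_terms)]
    # layer 0 is the root; remaining terms spread evenly over layers 1..n_layers-1
    layers: list[list[str]] = [[terms[0]]]
    if n_layers > 1:
        rest = np.array_split(np.arange(1, n_terms), n_layers - 1)
        layers += [[terms[i] for i in part] for part in rest]
    edges: list[tuple[str, str]] = []
    for depth in range(1, len(layers)):
        above = layers[depth - 1]
        for term in layers[depth]:
            n_parents = min(len(above), int(rng.integers(1, 3)))
            parents = rng.choice(len(above), size=n_parents, replace=False)
            edges.extend((term, above[p]) for p in sorted(parents))
    return DiseaseDAG(terms, edges)


def _disease_dag_from_factors(
    disease_ids: list[str], U: np.ndarray, seed: int
) -> DiseaseDAG:
    """Layered DAG whose leaves are the diseases, clustered by factor rows.

    A random scaffold DAG provides internal terms; diseases are grouped
    by k-means on their planted factor rows and attached under their
    cluster's scaffold leaf (a minority get a second parent), so
    factor-similar diseases share deep ancestors.
    """
    nd = len(disease_ids)
    n_clusters = max(2, min(nd, round(np.sqrt(nd))))
    scaffold = generate_dag(
        n_terms=max(3, n_clusters + 2), n_layers=3, seed=(seed + 1) % (2**31)
    )
    # scaffold leaves = terms that never appear as a parent
    parent_terms = {p for _, p in scaffold.parent_edges}
    leaves = [t for t in scaffold.terms if t not in parent_terms]
    km = KMeans(n_clusters=n_clusters, n_init=5, random_state=seed % (2**31))
    labels = km.fit_predict(U)
    rng = np.random.default_rng((seed + 2) % (2**31))
    terms = list(scaffold.terms) + list(disease_ids)
    edges = list(scaffold.parent_edges)
    for d, lab in zip(disease_ids, labels):
        primary = leaves[lab % len(leaves)]
        edges.append((d, primary))
        if len(leaves) > 1 and rng.uniform() < 0.2:
            other = leaves[int(rng.integers(len(leaves)))]
            if other != primary:
                edges.append((d, other))
    return DiseaseDAG(terms, edges)


def generate_dataset(
    nd: int,
    nm: int,
    rank: int,
    density: float,
    noise: float,
    seed: int,
) -> SyntheticDataset:
    """Generate a planted-structure dataset (associations + both similarity
    inputs), fully determined by ``seed``.

    Association sampling is redrawn (up to 10 attempts, with a warning)
    if it leaves a disease or miRNA with no association at all; failing
    all attempts means the requested density is infeasible.
    """
    if not (1 <= rank <= min(nd, nm)):
        raise ValueError(f"rank must lie in [1, {min(nd, nm)}], got {rank}")
    if not (0.0 < density < 1.0):
        raise ValueError(f"density must lie in (0, 1), got {density}")
    if noise < 0:
        raise ValueError(f"noise must be nonnegative, got {noise}")
    rng = np.random.default_rng(seed)
    disease_ids = [f"disease{i:04d}" for i in range(nd)]
    mirna_ids = [f"mirna{j:04d}" for j in range(nm)]

    U = rng.gamma(shape=2.0, scale=1.0, size=(nd, rank))
    V = rng.gamma(shape=2.0, scale=1.0, size=(nm, rank))
    latent = U @ V.T
    latent /= latent.max()
    probs = np.clip(density / latent.mean() * latent, 0.0, 1.0)

    values = (rng.uniform(size=(nd, nm)) < probs).astype(float)
    # A sparse Bernoulli draw routinely leaves a few entities with no
    # associations; those profiles are redrawn in place (conditioning each
    # on being nonempty) rather than rejecting the whole matrix, which at
    # realistic densities would almost never produce a clean draw.
    clean = False
    for attempt in range(10):
        zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
        for i in zero_rows:
            values[i] = (rng.uniform(size=nm) < probs[i]).astype(float)
        zero_cols = np.flatnonzero(values.sum(axis=0) == 0)
        for j in zero_cols:
            values[:, j] = (rng.uniform(size=nd) < probs[:, j]).astype(float)
        if zero_rows.size or zero_cols.size:
            warnings.warn(
                f"pass {attempt + 1}: resampled {zero_rows.size} empty disease "
                f"and {zero_cols.size} empty miRNA profiles",
                stacklevel=2,
            )
        if values.sum(axis=1).all() and values.sum(axis=0).all():
            clean = True
            break
    if not clean:
        raise ValueError(
            f"density {density} is infeasible: could not draw an association "
            "matrix without all-zero profiles in 10 resampling passes"
        )
    assoc = AssociationMatrix(values, disease_ids, mirna_ids)

    fun = cosine_similarity(V)
    if noise > 0:
        pert = rng.uniform(-noise, noise, size=(nm, nm))
        pert = (pert + pert.T) / 2.0
        fun = np.clip(fun + pert, 0.0, 1.0)
    fun = (fun + fun.T) / 2.0
    np.fill_diagonal(fun, 1.0)
    mirna_functional = SimilarityMatrix(fun, mirna_ids, view_name="functional")

    dag = _disease_dag_from_factors(disease_ids, U, seed)
    truth = {"U": U, "V": V, "latent": latent}
    return SyntheticDataset(assoc, mirna_functional, dag, truth, seed)


def latent_oracle_auc(dataset: SyntheticDataset) -> float:
    """Ranking AUC of the planted latent scores against the realized draw.

    Associations are sampled cell-wise with probability proportional to
    the latent scores, so an oracle that knows the planted factors
    exactly can do no better than ranking pairs by the latent score
    itself.  This AUC is therefore the ceiling for any held-out ranking
    on this dataset; how far below it a pipeline lands measures the
    pipeline, how far below 1 it sits measures the dataset's intrinsic
    signal.
    """
    from .evaluate import roc_auc

    return roc_auc(
        dataset.truth["latent"].ravel(), dataset.assoc.values.ravel()
    ).auc


def degree_preserving_rewire(
    assoc: AssociationMatrix, seed: int, n_swaps: int | None = None
) -> AssociationMatrix:
    """Shuffle the association 1s while preserving row and column degrees.

    Repeated checkerboard swaps: two associations (i1,j1), (i2,j2) are
    replaced by (i1,j2), (i2,j1) whenever the latter pair is absent.
    This destroys the planted low-rank structure but keeps every
    entity's interaction count, so GIP bandwidths are untouched — the
    null model for the recovery checks.
    """
    rng = np.random.default_rng(seed)
    A = assoc.values.copy()
    ones = [tuple(p) for p in np.argwhere(A == 1.0)]
    if n_swaps is None:
        n_swaps = 10 * len(ones)
    performed = 0
    attempts = 0
    max_attempts = 100 * n_swaps
    while performed < n_swaps and attempts < max_attempts:
        attempts += 1
        a, b = rng.integers(len(ones), size=2)
        (i1, j1), (i2, j2) = ones[a], ones[b]
        if i1 == i2 or j1 == j2 or A[i1, j2] == 1.0 or A[i2, j1] == 1.0:
            continue
        A[i1, j1] = A[i2, j2] = 0.0
        A[i1, j2] = A[i2, j1] = 1.0
        ones[a], ones[b] = (i1, j2), (i2, j1)
        performed += 1
    return AssociationMatrix(A, list(assoc.disease_ids), list(assoc.mirna_ids))


def dump_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the standard file formats; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": out / "associations.tsv",
        "mirna_functional": out / "mirna_functional_similarity.tsv",
        "dag_terms": out / "disease_terms.tsv",
        "dag_edges": out / "disease_term_edges.tsv",
    }
    sio.write_associations(dataset.assoc, paths["associations"])
    sio.write_similarity(dataset.mirna_functional, paths["mirna_functional"])
    sio.write_dag(dataset.disease_dag, paths["dag_terms"], paths["dag_edges"])
    return paths
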