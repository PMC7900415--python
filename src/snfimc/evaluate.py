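"""Cross-validation protocols and ROC/AUC evaluation.

Two protocols validate the pipeline against the verified associations:

* **global LOOCV** — each verified pair is held out in turn, the model is
  refitted without it, and the held-out pair's score is ranked against
  the candidate pool (every pair with no verified association).
* **repeated 5-fold CV** — the verified pairs are partitioned at random
  into five folds; each fold is masked in turn and its pairs are ranked
  against the candidate pool under that fold's model.  The partition is
  redrawn ``n_repeats`` times and the per-repeat AUCs are averaged.

By default the GIP kernel and the SNF fusion are recomputed from the
masked association matrix inside every fold, so no held-out information
reaches the similarity features ("recompute_similarity").  A static
mode reuses the full-data similarities — cheaper, but the held-out
pairs then leak into the GIP profiles; it exists for sensitivity
analysis only.

AUC is the tie-aware pairwise probability that a held-out positive
outscores a candidate (ties count half), which equals the trapezoidal
area under the ROC curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .containers import AssociationMatrix, SimilarityMatrix
from .imc import fit_imc
from .pipeline import PipelineConfig, build_similarities


@dataclass
class CVResult:
    """ROC curve and AUC from one evaluation run."""

    auc: float
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR), (0,0) .. (1,1)
    per_fold_aucs: list[float] | None = None
    per_repeat_aucs: list[float] | None = None
    n_repeats: int = 1
    seed: int | None = None
    config: dict[str, Any] | None = None

    def write_roc_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr:.17g}\t{tpr:.17g}\n")

    def summary(self) -> dict[str, Any]:
        return {
            "auc": self.auc,
            "per_fold_aucs": self.per_fold_aucs,
            "per_repeat_aucs": self.per_repeat_aucs,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "config": self.config,
        }

    def write_summary_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)


def roc_auc(scores, labels) -> CVResult:
    """ROC curve and tie-aware AUC for a flat score/label list.

    AUC = (#{pos > neg} + 1/2 #{pos = neg}) / (#pos * #neg), the
    trapezoidal area under the full (no intermediate points dropped)
    ROC curve.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain at least one positive and one negative")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return CVResult(auc=auc, roc_points=points)


def _candidate_percentiles(pos_scores: np.ndarray, cand_scores: np.ndarray) -> np.ndarray:
    """Tie-aware rank percentile of each positive within the candidate pool."""
    cand_sorted = np.sort(cand_scores)
    n = cand_sorted.size
    lo = np.searchsorted(cand_sorted, pos_scores, side="left")
    hi = np.searchsorted(cand_sorted, pos_scores, side="right")
    return (lo + 0.5 * (hi - lo)) / n


def _staircase_roc(percentiles: np.ndarray) -> tuple[float, np.ndarray]:
    """ROC of held-out positives against the empirical candidate distribution.

    Each positive carries its percentile among the candidates it was
    ranked against; sweeping the percentile threshold gives a staircase
    whose trapezoidal area equals the mean percentile — the pairwise AUC.
    """
    percentiles = np.asarray(percentiles, dtype=float)
    p_total = percentiles.size
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    vals, counts = np.unique(-percentiles, return_counts=True)
    cum = np.cumsum(counts)
    y = 0.0
    for neg_p, c in zip(vals, cum):  # descending percentile order
        x = 1.0 + neg_p  # 1 - p
        points.append((x, y))
        y = float(c) / p_total  # exact ratio of counts, no drift
        points.append((x, y))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return float(percentiles.mean()), np.array(points)


def fold_partition(n_items: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Uniform random partition of item indices into ``n_folds`` folds."""
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n_items), n_folds)


def _fold_model_scores(
    assoc_masked: AssociationMatrix,
    disease_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    config: PipelineConfig,
    static_sims: tuple | None,
) -> np.ndarray:
    if static_sims is None:
        sd, sm = build_similarities(assoc_masked, disease_sim, mirna_sim, config)
    else:
        sd, sm = static_sims
    factors = fit_imc(assoc_masked, sd, sm, config.imc)
    return sd.values @ factors.U @ factors.V.T @ sm.values.T


def global_loocv(
    assoc: AssociationMatrix,
    disease_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    config: PipelineConfig | None = None,
    recompute_similarity: bool = True,
    max_folds: int | None = None,
    seed: int = 0,
) -> CVResult:
    """Global leave-one-out CV: every verified pair held out in turn.

    Each held-out pair is ranked against the candidate pool (all pairs
    with no verified association in the full matrix), scored by that
    fold's model; AUC aggregates all folds' comparisons.  ``max_folds``
    subsamples the held-out pairs (seeded) — an *approximation* for
    quick runs, not the full protocol.
    """
    config = config or PipelineConfig()
    positives = assoc.positive_pairs()
    if len(positives) < 2:
        raise ValueError("global LOOCV needs at least 2 verified associations")
    if max_folds is not None and max_folds < len(positives):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(positives), size=max_folds, replace=False)
        positives = positives[np.sort(keep)]
    cand_mask = assoc.values == 0.0
    static = None
    if not recompute_similarity:
        static = build_similarities(assoc, disease_sim, mirna_sim, config)
    percentiles = np.empty(len(positives))
    for k, (i, j) in enumerate(positives):
        masked = assoc.masked([[i, j]])
        S = _fold_model_scores(masked, disease_sim, mirna_sim, config, static)
        percentiles[k] = _candidate_percentiles(
            np.array([S[i, j]]), S[cand_mask]
        )[0]
    auc, points = _staircase_roc(percentiles)
    return CVResult(
        auc=auc, roc_points=points, n_repeats=1, seed=seed,
        config=config.to_dict(),
    )


def five_fold_cv(
    assoc: AssociationMatrix,
    disease_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    config: PipelineConfig | None = None,
    n_repeats: int = 1,
    seed: int = 0,
    recompute_similarity: bool = True,
    n_folds: int = 5,
) -> CVResult:
    """Repeated 5-fold CV over the verified associations.

    Per repeat, the verified pairs are split uniformly at random into
    ``n_folds`` folds from the repeat seed (master seed + repeat index);
    per fold, the fold's positives are masked, the model refitted, and
    the fold positives ranked against the candidate pool.  The repeat
    AUC pools the five folds' comparisons; the reported AUC is the mean
    over repeats.
    """
    config = config or PipelineConfig()
    positives = assoc.positive_pairs()
    if len(positives) < n_folds:
        raise ValueError(f"{n_folds}-fold CV needs at least {n_folds} positives")
    cand_mask = assoc.values == 0.0
    static = None
    if not recompute_similarity:
        static = build_similarities(assoc, disease_sim, mirna_sim, config)
    per_fold_aucs: list[float] = []
    per_repeat_aucs: list[float] = []
    all_percentiles: list[np.ndarray] = []
    for rep in range(n_repeats):
        rep_percentiles: list[np.ndarray] = []
        for fold in fold_partition(len(positives), n_folds, seed + rep):
            test_pairs = positives[fold]
            masked = assoc.masked(test_pairs)
            S = _fold_model_scores(masked, disease_sim, mirna_sim, config, static)
            pctl = _candidate_percentiles(
                S[test_pairs[:, 0], test_pairs[:, 1]], S[cand_mask]
            )
            rep_percentiles.append(pctl)
            per_fold_aucs.append(float(pctl.mean()))
        rep_all = np.concatenate(rep_percentiles)
        per_repeat_aucs.append(float(rep_all.mean()))
        all_percentiles.append(rep_all)
    _, points = _staircase_roc(np.concatenate(all_percentiles))
    return CVResult(
        auc=float(np.mean(per_repeat_aucs)),
        roc_points=points,
        per_fold_aucs=per_fold_aucs,
        per_repeat_aucs=per_repeat_aucs,
        n_repeats=n_repeats,
        seed=seed,
        config=config.to_dict(),
    )
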