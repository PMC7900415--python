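"""ROC/AUC machinery and the cross-validation protocols."""

import numpy as np
import pytest

import snfimc as s
from snfimc.evaluate import (
    _candidate_percentiles,
    _staircase_roc,
    fold_partition,
)


def brute_auc(scores, labels):
    """All-pairs Mann-Whitney count with half-weight ties."""
    pos = [x for x, l in zip(scores, labels) if l == 1]
    neg = [x for x, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert s.roc_auc([0.9, 0.1], [1, 0]).auc == pytest.approx(1.0)

    def test_all_ties_half(self):
        assert s.roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 1]).auc == pytest.approx(0.5)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        r = s.roc_auc(rng.uniform(size=10_000),
                      rng.integers(0, 2, size=10_000))
        assert abs(r.auc - 0.5) < 0.02

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="positive"):
            s.roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_pairwise_oracle_including_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        # coarse grid forces ties
        scores = rng.integers(0, 5, size=n) / 4.0
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        r = s.roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)

    def test_roc_points_envelope_and_area(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=200)
        labels = (rng.uniform(size=200) < 0.4).astype(int)
        r = s.roc_auc(scores, labels)
        pts = r.roc_points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
        assert r.auc == pytest.approx(
            np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-10)

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x ** 3,
                                           lambda x: 2 * x + 7])
    def test_monotone_transform_invariance(self, transform):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=300)
        labels = (rng.uniform(size=300) < 0.3).astype(int)
        assert s.roc_auc(transform(scores), labels).auc == pytest.approx(
            s.roc_auc(scores, labels).auc, abs=1e-12)


class TestPercentileMachinery:
    def test_percentiles_match_pairwise_counts(self):
        rng = np.random.default_rng(5)
        cand = rng.integers(0, 10, size=50) / 9.0
        pos = rng.integers(0, 10, size=8) / 9.0
        got = _candidate_percentiles(pos, cand)
        for p, g in zip(pos, got):
            expected = (np.sum(cand < p) + 0.5 * np.sum(cand == p)) / len(cand)
            assert g == pytest.approx(expected, abs=1e-15)

    def test_staircase_area_equals_mean_percentile(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            pctls = rng.uniform(size=rng.integers(1, 40))
            auc, pts = _staircase_roc(pctls)
            assert auc == pytest.approx(pctls.mean(), abs=1e-15)
            assert auc == pytest.approx(
                np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-10)
            assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
            assert (np.diff(pts[:, 0]) >= 0).all()
            assert (np.diff(pts[:, 1]) >= 0).all()


class TestFoldPartition:
    @pytest.mark.parametrize("n,k", [(23, 5), (100, 5), (5, 5)])
    def test_every_item_in_exactly_one_fold(self, n, k):
        folds = fold_partition(n, k, seed=1)
        allidx = np.concatenate(folds)
        assert len(folds) == k
        assert sorted(allidx) == list(range(n))

    def test_seeded_determinism(self):
        a = fold_partition(40, 5, seed=9)
        b = fold_partition(40, 5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


@pytest.fixture(scope="module")
def fast_cfg():
    return s.PipelineConfig(
        snf=s.SNFConfig(n_iterations=5, n_neighbors=5),
        imc=s.IMCConfig(rank=4, max_iter=60, seed=0),
    )


class TestProtocols:
    def test_five_fold_deterministic(self, small_inputs, fast_cfg):
        assoc, sem, fun = small_inputs
        r1 = s.five_fold_cv(assoc, sem, fun, fast_cfg, n_repeats=1, seed=5)
        r2 = s.five_fold_cv(assoc, sem, fun, fast_cfg, n_repeats=1, seed=5)
        assert r1.auc == r2.auc
        np.testing.assert_array_equal(r1.roc_points, r2.roc_points)

    def test_five_fold_result_invariants(self, small_inputs, fast_cfg):
        assoc, sem, fun = small_inputs
        r = s.five_fold_cv(assoc, sem, fun, fast_cfg, n_repeats=2, seed=5)
        assert 0.0 <= r.auc <= 1.0
        assert len(r.per_repeat_aucs) == 2
        assert len(r.per_fold_aucs) == 10
        assert r.auc == pytest.approx(np.mean(r.per_repeat_aucs), abs=1e-12)
        pts = r.roc_points
        assert np.mean(np.concatenate([r.per_repeat_aucs])) == pytest.approx(
            np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-10)

    def test_loocv_restores_input_matrix(self, small_inputs, fast_cfg):
        assoc, sem, fun = small_inputs
        before = assoc.values.copy()
        s.global_loocv(assoc, sem, fun, fast_cfg, max_folds=6, seed=2)
        np.testing.assert_array_equal(assoc.values, before)

    def test_loocv_deterministic_subsample(self, small_inputs, fast_cfg):
        assoc, sem, fun = small_inputs
        r1 = s.global_loocv(assoc, sem, fun, fast_cfg, max_folds=6, seed=2)
        r2 = s.global_loocv(assoc, sem, fun, fast_cfg, max_folds=6, seed=2)
        assert r1.auc == r2.auc

    def test_uninformative_scores_give_chance_auc(self):
        # constant score matrix: every percentile is exactly 1/2
        pctls = _candidate_percentiles(np.full(10, 0.3), np.full(100, 0.3))
        auc, _ = _staircase_roc(pctls)
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_fold_masking_is_leak_free(self, small_inputs, fast_cfg):
        # the fold's GIP profiles must come from the masked matrix: the
        # held-out positives contribute nothing to similarity or fitting
        assoc, sem, fun = small_inputs
        pairs = assoc.positive_pairs()[:4]
        masked = assoc.masked(pairs)
        assert (masked.values[pairs[:, 0], pairs[:, 1]] == 0).all()
        sd_m, sm_m = s.build_similarities(masked, sem, fun, fast_cfg)
        # independent recomputation from the masked values only
        gkd = s.gip_similarity(masked, "disease",
                               fast_cfg.gamma_prime_disease)
        sd_ref = s.snf_fuse(sem, gkd, fast_cfg.snf)
        np.testing.assert_array_equal(sd_m.values, sd_ref.values)
        # and the full-data similarities differ, i.e. masking matters
        sd_full, _ = s.build_similarities(assoc, sem, fun, fast_cfg)
        assert np.abs(sd_full.values - sd_m.values).max() > 0

    def test_five_fold_consistent_with_loocv(self, small_inputs, fast_cfg):
        # both protocols estimate the same held-out ranking quantity and
        # should agree closely on one dataset
        assoc, sem, fun = small_inputs
        cv = s.five_fold_cv(assoc, sem, fun, fast_cfg, n_repeats=2, seed=1)
        loo = s.global_loocv(assoc, sem, fun, fast_cfg, seed=1)
        assert abs(cv.auc - loo.auc) < 0.05

    def test_too_few_positives_error(self, small_inputs, fast_cfg):
        _, sem, fun = small_inputs
        tiny = s.AssociationMatrix(
            np.eye(len(sem.ids), len(fun.ids)) * 0.0, sem.ids, fun.ids
        )
        with pytest.raises(ValueError):
            s.five_fold_cv(tiny, sem, fun, fast_cfg)
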