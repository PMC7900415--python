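"""IMC solver: objective algebra, update fixed points, monotonicity,
planted-structure recovery, and inductive scoring."""

import numpy as np
import pytest

import snfimc as s
from conftest import random_similarity


def random_instance(seed, nd=8, nm=6, r=3):
    rng = np.random.default_rng(seed)
    A = (rng.uniform(size=(nd, nm)) < 0.3).astype(float)
    Sd = random_similarity(nd, rng).values
    Sm = random_similarity(nm, rng).values
    U = rng.uniform(size=(nd, r))
    V = rng.uniform(size=(nm, r))
    return A, Sd, Sm, U, V


class TestObjective:
    def test_zero_factors_gives_half_association_count(self):
        A, Sd, Sm, U, V = random_instance(0)
        phi = s.imc_objective(A, Sd, Sm, np.zeros_like(U), np.zeros_like(V),
                              1.0, 1.0)
        assert phi == pytest.approx(0.5 * A.sum(), abs=1e-12)

    def test_exact_reconstruction_zero_objective(self):
        A, Sd, Sm, U, V = random_instance(1)
        A_exact = Sd @ U @ V.T @ Sm.T
        # not a binary matrix; evaluate the objective on raw arrays
        phi = s.imc_objective(A_exact, Sd, Sm, U, V, 0.0, 0.0)
        assert phi == pytest.approx(0.0, abs=1e-18)

    def test_linear_in_lambda1(self):
        A, Sd, Sm, U, V = random_instance(2)
        p1 = s.imc_objective(A, Sd, Sm, U, V, 1.0, 0.5)
        p2 = s.imc_objective(A, Sd, Sm, U, V, 2.0, 0.5)
        assert p2 - p1 == pytest.approx(0.5 * np.sum(U * U), rel=1e-12)

    def test_shape_mismatch_errors(self):
        A, Sd, Sm, U, V = random_instance(3)
        with pytest.raises(ValueError, match="conform"):
            s.imc_objective(A, Sd[:-1, :-1], Sm, U, V, 1.0, 1.0)


class TestUpdates:
    def test_zero_factor_is_fixed_point(self):
        A, Sd, Sm, U, V = random_instance(4)
        np.testing.assert_array_equal(
            s.update_V(A, Sd, Sm, U, np.zeros_like(V), 1.0), 0.0
        )
        np.testing.assert_array_equal(
            s.update_U(A, Sd, Sm, np.zeros_like(U), V, 1.0), 0.0
        )

    def test_stationary_ratio_leaves_factor_unchanged(self):
        # with A = Sd U V' Sm' and no regularization, numerator equals
        # denominator elementwise, so the update is the identity
        _, Sd, Sm, U, V = random_instance(5)
        A = Sd @ U @ V.T @ Sm.T
        np.testing.assert_allclose(s.update_V(A, Sd, Sm, U, V, 0.0), V,
                                   rtol=1e-9)
        np.testing.assert_allclose(s.update_U(A, Sd, Sm, U, V, 0.0), U,
                                   rtol=1e-9)

    @pytest.mark.parametrize("lam", [0.0, 0.5])
    def test_single_update_never_increases_objective(self, lam):
        for seed in range(100):
            A, Sd, Sm, U, V = random_instance(seed)
            before = s.imc_objective(A, Sd, Sm, U, V, lam, lam)
            V2 = s.update_V(A, Sd, Sm, U, V, lam)
            mid = s.imc_objective(A, Sd, Sm, U, V2, lam, lam)
            U2 = s.update_U(A, Sd, Sm, U, V2, lam)
            after = s.imc_objective(A, Sd, Sm, U2, V2, lam, lam)
            assert mid <= before * (1 + 1e-9)
            assert after <= mid * (1 + 1e-9)

    def test_outputs_nonnegative(self):
        A, Sd, Sm, U, V = random_instance(6)
        assert (s.update_V(A, Sd, Sm, U, V, 0.3) >= 0).all()
        assert (s.update_U(A, Sd, Sm, U, V, 0.3) >= 0).all()


class TestFit:
    def test_zero_target_decays(self):
        rng = np.random.default_rng(7)
        A = np.zeros((6, 5))
        Sd = random_similarity(6, rng).values
        Sm = random_similarity(5, rng).values
        f = s.fit_imc(A, Sd, Sm, s.IMCConfig(rank=2, lambda1=1.0, lambda2=1.0,
                                             seed=0))
        assert f.objective_trace[-1] <= f.objective_trace[0]
        assert np.abs(f.U).max() < 1e-6 and np.abs(f.V).max() < 1e-6

    def test_trace_non_increasing_and_deterministic(self, small_inputs):
        assoc, sem, fun = small_inputs
        sd, sm = s.build_similarities(assoc, sem, fun)
        cfg = s.IMCConfig(rank=5, seed=3, max_iter=100)
        f1 = s.fit_imc(assoc, sd, sm, cfg)
        f2 = s.fit_imc(assoc, sd, sm, cfg)
        np.testing.assert_array_equal(f1.U, f2.U)
        np.testing.assert_array_equal(f1.V, f2.V)
        tr = np.array(f1.objective_trace)
        assert (tr[1:] <= tr[:-1] * (1 + 1e-9)).all()

    def test_planted_exact_rank_recovery(self):
        rng = np.random.default_rng(11)
        U0 = rng.uniform(size=(20, 3))
        V0 = rng.uniform(size=(25, 3))
        A = U0 @ V0.T
        I_d, I_m = np.eye(20), np.eye(25)
        cfg = s.IMCConfig(rank=3, lambda1=0.0, lambda2=0.0, seed=5,
                          max_iter=2000)
        f = s.fit_imc(A, I_d, I_m, cfg)
        resid = np.linalg.norm(A - f.U @ f.V.T) / np.linalg.norm(A)
        assert resid < 0.05

    def test_rank3_beats_rank1(self):
        rng = np.random.default_rng(12)
        A = rng.uniform(size=(20, 3)) @ rng.uniform(size=(25, 3)).T
        I_d, I_m = np.eye(20), np.eye(25)
        fits = {
            r: s.fit_imc(A, I_d, I_m,
                         s.IMCConfig(rank=r, lambda1=0.0, lambda2=0.0,
                                     seed=5, max_iter=2000))
            for r in (1, 3)
        }
        assert fits[3].objective_trace[-1] < fits[1].objective_trace[-1]

    def test_rank_exceeding_dimensions_errors(self):
        with pytest.raises(ValueError, match="rank"):
            s.fit_imc(np.zeros((3, 4)), np.eye(3), np.eye(4),
                      s.IMCConfig(rank=5))


class TestPrediction:
    def test_identity_features_reduce_to_uv(self):
        rng = np.random.default_rng(13)
        f = s.IMCFactors(rng.uniform(size=(6, 2)), rng.uniform(size=(5, 2)),
                         [0.0], 0)
        sc = s.predict_scores(np.eye(6), np.eye(5), f)
        np.testing.assert_allclose(sc.values, f.U @ f.V.T, atol=1e-15)

    def test_matches_pairwise_double_loop(self):
        rng = np.random.default_rng(14)
        Sd = random_similarity(7, rng).values
        Sm = random_similarity(9, rng).values
        f = s.IMCFactors(rng.uniform(size=(7, 3)), rng.uniform(size=(9, 3)),
                         [0.0], 0)
        sc = s.predict_scores(Sd, Sm, f).values
        M = f.U @ f.V.T
        for i in range(7):
            for j in range(9):
                assert sc[i, j] == pytest.approx(Sd[i] @ M @ Sm[j], abs=1e-12)

    def test_scores_nonnegative(self, small_inputs):
        assoc, sem, fun = small_inputs
        scores, _ = s.predict(assoc, sem, fun,
                              s.PipelineConfig(imc=s.IMCConfig(rank=4,
                                                               max_iter=50)))
        assert (scores.values >= 0).all()

    def test_novel_disease_indicator_selects_row(self):
        rng = np.random.default_rng(15)
        Sd = random_similarity(6, rng).values
        Sm = random_similarity(5, rng).values
        f = s.IMCFactors(rng.uniform(size=(6, 2)), rng.uniform(size=(5, 2)),
                         [0.0], 0)
        full = s.predict_scores(Sd, Sm, f).values
        e2 = np.zeros(6)
        e2[2] = 1.0
        got = s.predict_novel_disease(Sd[2], Sm, f)
        np.testing.assert_allclose(got, full[2], atol=1e-12)
        # a bare indicator selects row 2 of U V' Sm'
        np.testing.assert_allclose(
            s.predict_novel_disease(e2, Sm, f),
            (f.U @ f.V.T @ Sm.T)[2], atol=1e-15
        )

    def test_novel_disease_linearity_and_zero(self):
        rng = np.random.default_rng(16)
        Sm = random_similarity(5, rng).values
        f = s.IMCFactors(rng.uniform(size=(6, 2)), rng.uniform(size=(5, 2)),
                         [0.0], 0)
        e0, e1 = np.eye(6)[0], np.eye(6)[1]
        avg = s.predict_novel_disease((e0 + e1) / 2, Sm, f)
        np.testing.assert_allclose(
            avg,
            (s.predict_novel_disease(e0, Sm, f)
             + s.predict_novel_disease(e1, Sm, f)) / 2, atol=1e-15)
        np.testing.assert_array_equal(
            s.predict_novel_disease(np.zeros(6), Sm, f), 0.0)

    def test_length_mismatch_errors(self):
        f = s.IMCFactors(np.ones((6, 2)), np.ones((5, 2)), [0.0], 0)
        with pytest.raises(ValueError, match="length"):
            s.predict_novel_disease(np.ones(4), np.eye(5), f)
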