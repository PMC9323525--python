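"""PARAFAC fitting, diagnostics, component matching and score tests."""

import numpy as np
import pytest

from ateem.parafac import (
    ParafacModel,
    compare_class_scores,
    congruence_matrix,
    core_consistency,
    explained_variance,
    fit_parafac,
    match_components,
    select_n_components,
    split_half,
    tucker_congruence,
)
from ateem.errors import ClassError, DimensionError

from conftest import FIT_KW


def truth_model(sim):
    return ParafacModel(
        sim.truth.scores.shape[1],
        sim.truth.scores,
        sim.truth.em_profiles,
        sim.truth.ex_profiles,
    )


def exact_rank_f(F, seed=0, shape=(9, 11, 7)):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.5, 2.0, (shape[0], F))
    B = rng.uniform(0.1, 1.0, (shape[1], F))
    C = rng.uniform(0.1, 1.0, (shape[2], F))
    return np.einsum("if,jf,kf->ijk", A, B, C), A, B, C


class TestCongruence:
    def test_self_and_orthogonal(self):
        v = np.array([1.0, 2.0, 3.0])
        assert tucker_congruence(v, v) == pytest.approx(1.0)
        assert tucker_congruence([1, 0], [0, 1]) == pytest.approx(0.0)


class TestFitParafac:
    def test_rank1_closed_form_recovery(self, rank1_array):
        X, a, b, c = rank1_array
        m = fit_parafac(X, 1, seed=0, n_starts=2, tol=1e-12, max_iter=500)
        # recovered score vector equals true a up to scale
        ratio = m.scores[:, 0] / (a * np.linalg.norm(b) * np.linalg.norm(c))
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)
        assert abs(tucker_congruence(m.em_loadings[:, 0], b)) > 1 - 1e-9

    def test_noiseless_rank4_reaches_exact_fit(self):
        X, A, B, C = exact_rank_f(4, seed=1, shape=(12, 16, 10))
        m = fit_parafac(X, 4, seed=3, n_starts=4, tol=1e-12, max_iter=2000)
        assert m.fit_percent >= 99.99
        tm = ParafacModel(4, A, B / np.linalg.norm(B, axis=0),
                          C / np.linalg.norm(C, axis=0))
        _, ce, cx = match_components(m, tm)
        assert min(ce.min(), cx.min()) > 0.99

    def test_component_recovery_on_default_synthetic(self, sim, model4):
        _, ce, cx = match_components(model4, truth_model(sim))
        assert min(ce.min(), cx.min()) > 0.95

    def test_processed_class_browning_scores_match_generator(self, sim, model4):
        perm, _, _ = match_components(model4, truth_model(sim))
        col = int(np.where(perm == 3)[0][0])
        recovered = model4.scores[np.array(sim.labels) == "processed", col]
        true = sim.truth.scores[np.array(sim.labels) == "processed", 3]
        # recovery error far below sampling spread of the configured dist
        assert abs(recovered.mean() - true.mean()) < 0.05 * true.mean()

    def test_objective_monotone_nonincreasing(self, model4):
        h = model4.sse_history
        assert np.all(np.diff(h) <= np.abs(h[:-1]) * 1e-7 + 1e-9)

    def test_reconstruction_invariant_to_column_permutation(self, model4):
        perm = np.array([2, 0, 3, 1])
        permuted = ParafacModel(
            4,
            model4.scores[:, perm],
            model4.em_loadings[:, perm],
            model4.ex_loadings[:, perm],
        )
        np.testing.assert_allclose(
            permuted.reconstruct(), model4.reconstruct(), rtol=1e-12
        )

    def test_nonneg_constraint_and_unit_norm_loadings(self, model4):
        assert np.all(model4.scores >= 0)
        assert np.all(model4.em_loadings >= 0)
        assert np.all(model4.ex_loadings >= 0)
        np.testing.assert_allclose(
            np.linalg.norm(model4.em_loadings, axis=0), 1.0, rtol=1e-10
        )
        np.testing.assert_allclose(
            np.linalg.norm(model4.ex_loadings, axis=0), 1.0, rtol=1e-10
        )

    def test_dimension_errors(self):
        X = np.zeros((3, 4, 5))
        with pytest.raises(DimensionError):
            fit_parafac(X + 1.0, 4, n_starts=1, max_iter=5)
        with pytest.raises(DimensionError):
            fit_parafac(X + 1.0, 0)


class TestExplainedVariance:
    def test_exact_model_gives_100(self):
        X, A, B, C = exact_rank_f(2, seed=5)
        m = fit_parafac(X, 2, seed=1, n_starts=2, tol=1e-13, max_iter=2000)
        assert explained_variance(m, X) == pytest.approx(100.0, abs=1e-6)

    def test_zero_model_gives_0(self):
        X, *_ = exact_rank_f(2, seed=6)
        m = ParafacModel(1, np.zeros((X.shape[0], 1)),
                         np.zeros((X.shape[1], 1)), np.zeros((X.shape[2], 1)))
        assert explained_variance(m, X) == pytest.approx(0.0)

    def test_matches_cell_by_cell_summation(self, sim, model4, ds_masked):
        Xa = ds_masked.masked_array()
        R = model4.reconstruct()
        ssr = sst = 0.0  # brute-force loop oracle
        n, J, K = Xa.shape
        for i in range(n):
            for j in range(0, J, 7):
                for k in range(K):
                    if np.isfinite(Xa[i, j, k]):
                        ssr += (Xa[i, j, k] - R[i, j, k]) ** 2
                        sst += Xa[i, j, k] ** 2
        sub = 100.0 * (1 - ssr / sst)
        # same computation vectorised over the full grid
        full = explained_variance(model4, Xa)
        assert full == pytest.approx(model4.fit_percent, abs=1e-6)
        assert sub == pytest.approx(full, abs=0.2)  # subsampled rows


class TestCoreConsistency:
    def test_exact_trilinear_gives_100(self):
        X, *_ = exact_rank_f(3, seed=7)
        m = fit_parafac(X, 3, seed=2, n_starts=3, tol=1e-13, max_iter=3000)
        assert core_consistency(m, X) == pytest.approx(100.0, abs=0.1)

    def test_one_component_always_100(self, sim):
        Xa = sim.dataset.array
        m = fit_parafac(Xa, 1, seed=0, n_starts=1, tol=1e-8, max_iter=300)
        assert core_consistency(m, Xa) == pytest.approx(100.0, abs=1e-6)

    def test_overfactored_model_drops_sharply(self, ds_masked, model4):
        m5 = fit_parafac(ds_masked, 5, seed=11, **FIT_KW)
        cc5 = m5.corcondia
        assert np.isnan(cc5) or cc5 < 50.0
        assert model4.corcondia > 90.0

    def test_scale_invariance(self, ds_masked, model4):
        Xa = ds_masked.masked_array()
        scaled = ParafacModel(
            4, model4.scores * 37.5, model4.em_loadings, model4.ex_loadings
        )
        a = core_consistency(model4, Xa)
        b = core_consistency(scaled, Xa * 37.5)
        assert a == pytest.approx(b, abs=1e-6)

    def test_least_squares_core_oracle(self):
        # independent oracle: explicit dense regression for the full core
        X, A, B, C = exact_rank_f(2, seed=8, shape=(6, 5, 4))
        m = fit_parafac(X, 2, seed=3, n_starts=2, tol=1e-13, max_iter=2000)
        D = np.einsum("id,je,kf->ijkdef", m.scores, m.em_loadings,
                      m.ex_loadings).reshape(-1, 8)
        g, *_ = np.linalg.lstsq(D, X.ravel(), rcond=None)
        t = np.zeros(8)
        t[[0, 7]] = 1.0
        oracle = 100.0 * (1 - ((g - t) ** 2).sum() / 2.0)
        assert core_consistency(m, X) == pytest.approx(oracle, abs=1e-8)


class TestSplitHalf:
    def test_duplicated_samples_give_full_similarity(self):
        X, A, B, C = exact_rank_f(2, seed=9, shape=(6, 8, 7))
        Xdup = np.concatenate([X, X], axis=0)
        sim_pct = split_half(Xdup, 2, seed=0, n_starts=2, tol=1e-10,
                             max_iter=1500)
        assert sim_pct > 99.5

    def test_default_synthetic_is_stable(self, ds_masked):
        sim_pct = split_half(ds_masked, 4, seed=5, **FIT_KW)
        assert sim_pct >= 76.3

    def test_too_few_samples(self):
        X = np.ones((5, 6, 6))
        with pytest.raises(DimensionError):
            split_half(X, 3)


class TestSelectAndMatch:
    def test_exact_rank2_scan_selects_2(self):
        X, *_ = exact_rank_f(2, seed=10, shape=(10, 9, 8))
        X = X + np.random.default_rng(0).normal(0, 1e-4, X.shape)
        best, table = select_n_components(
            X, (1, 2, 3, 4), seed=1, n_starts=2, tol=1e-9, max_iter=800
        )
        assert best == 2

    def test_single_candidate(self, rank1_array):
        X = rank1_array[0]
        best, _ = select_n_components(X, (1,), seed=0, n_starts=1,
                                      tol=1e-8, max_iter=200)
        assert best == 1

    def test_match_identity_and_swap(self, model4):
        perm, ce, cx = match_components(model4, model4)
        np.testing.assert_array_equal(perm, np.arange(4))
        np.testing.assert_allclose(np.concatenate([ce, cx]), 1.0, rtol=1e-12)
        swap = np.array([1, 0, 3, 2])
        swapped = ParafacModel(4, model4.scores[:, swap],
                               model4.em_loadings[:, swap],
                               model4.ex_loadings[:, swap])
        perm2, _, _ = match_components(model4, swapped)
        np.testing.assert_array_equal(perm2, swap)

    def test_congruence_matrix_columns(self):
        U = np.eye(3)
        V = np.array([[0.0, 1.0, 0], [1.0, 0, 0], [0, 0, 1.0]])
        np.testing.assert_allclose(congruence_matrix(U, V), V)


class TestClassScores:
    def test_identical_groups_not_significant(self):
        scores = np.tile(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])[:, None],
                         (1, 2))
        labels = ["a"] * 3 + ["b"] * 3
        table = compare_class_scores(scores, labels)
        np.testing.assert_allclose(table["t"], 0.0, atol=1e-12)
        assert not table["significant"].any()

    def test_textbook_t_formula(self):
        g1, g2 = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        scores = np.array(g1 + g2)[:, None]
        labels = ["a"] * 3 + ["b"] * 3
        table = compare_class_scores(scores, labels)
        # hand computation: pooled-variance two-sample t
        m1, m2 = np.mean(g1), np.mean(g2)
        s2 = (np.var(g1, ddof=1) * 2 + np.var(g2, ddof=1) * 2) / 4
        t_hand = (m1 - m2) / np.sqrt(s2 * (1 / 3 + 1 / 3))
        assert table["t"].iloc[0] == pytest.approx(t_hand, rel=1e-12)

    def test_default_synthetic_significance_pattern(self, sim, model4):
        perm, _, _ = match_components(model4, truth_model(sim))
        order = [int(np.where(perm == f)[0][0]) for f in range(4)]
        table = compare_class_scores(model4.scores[:, order], sim.labels)
        assert bool(table["significant"].iloc[3])  # browning component
        assert not bool(table["significant"].iloc[0])

    def test_empty_class_rejected(self):
        with pytest.raises(ClassError):
            compare_class_scores(np.ones((3, 2)), ["a", "a", "a"])
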