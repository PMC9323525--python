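"""PLS-DA fitting, cross-validation, confusion metrics and VIP."""

import numpy as np
import pytest

from ateem.core import WavelengthGrid
from ateem.errors import ClassError, DimensionError
from ateem.plsda import (
    ClassEncoding,
    ConfusionMatrix,
    cross_validate,
    fit_plsda,
    misclassification_error,
    sensitivity,
    specificity,
    vip_eem_map,
)


def two_class_data(n1=8, n2=10, p=6, gap=4.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, noise, (n1 + n2, p))
    X[n1:, 0] += gap
    labels = ["direct"] * n1 + ["processed"] * n2
    return X, ClassEncoding.from_labels(labels)


class TestEncoding:
    def test_dummy_rows_sum_to_one_fixed_order(self):
        enc = ClassEncoding.from_labels(["processed", "direct", "processed"])
        assert enc.classes == ("direct", "processed")
        np.testing.assert_array_equal(enc.Y.sum(axis=1), 1.0)
        np.testing.assert_array_equal(enc.Y[:, 1], [1, 0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ClassError):
            ClassEncoding.from_labels(["a", "a"])


class TestMetrics:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(tp=14, tn=20, fp=0, fn=1), 0.93),
            (ConfusionMatrix(tp=5, tn=1, fp=1, fn=0), 1.00),
            (ConfusionMatrix(tp=0, tn=1, fp=1, fn=5), 0.00),
        ],
    )
    def test_sensitivity(self, cm, expected):
        assert round(sensitivity(cm), 2) == expected

    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(tp=15, tn=17, fp=3, fn=0), 0.85),
            (ConfusionMatrix(tp=14, tn=19, fp=1, fn=1), 0.95),
            (ConfusionMatrix(tp=1, tn=9, fp=0, fn=0), 1.00),
        ],
    )
    def test_specificity(self, cm, expected):
        assert round(specificity(cm), 2) == expected

    @pytest.mark.parametrize(
        "errors,expected",
        [(1, 0.029), (3, 0.086), (0, 0.0)],
    )
    def test_misclassification_out_of_35(self, errors, expected):
        cm = ConfusionMatrix(tp=15, tn=20 - errors, fp=errors, fn=0)
        assert round(misclassification_error(cm), 3) == expected

    def test_undefined_cases(self):
        with pytest.raises(DimensionError):
            sensitivity(ConfusionMatrix(tp=0, tn=3, fp=1, fn=0))
        with pytest.raises(DimensionError):
            specificity(ConfusionMatrix(tp=2, tn=0, fp=0, fn=1))

    def test_agrees_with_brute_force_label_counting(self, sim, ds_interp):
        from ateem.core import unfold

        X = unfold(ds_interp).values
        enc = ClassEncoding.from_labels(sim.labels)
        m = fit_plsda(X, enc, 4)
        pred = np.asarray(m.training_predictions)
        truth = np.asarray(sim.labels)
        cm = m.confusion(sim.labels, positive_class="direct")
        assert cm.tp == int(np.sum((truth == "direct") & (pred == "direct")))
        assert cm.fn == int(np.sum((truth == "direct") & (pred == "processed")))
        assert cm.fp == int(np.sum((truth == "processed") & (pred == "direct")))
        assert misclassification_error(cm) == pytest.approx(
            np.mean(pred != truth)
        )


class TestFitPlsda:
    def test_separated_classes_zero_training_error(self):
        X, enc = two_class_data(noise=0.05)
        m = fit_plsda(X, enc, 2)
        assert m.training_predictions == list(enc.labels)

    def test_univariate_one_lv_is_a_threshold(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 20)
        labels = ["direct" if v < 5 else "processed" for v in x]
        enc = ClassEncoding.from_labels(labels)
        m = fit_plsda(x[:, None], enc, 1)
        # closed form: scores predictions are linear in x, so the argmax
        # decision is a threshold where the two dummy predictions cross
        coef = m.regression_coefficients
        thr = m.x_mean[0] + (
            (m.intercept[1] - m.intercept[0]) / (coef[0, 0] - coef[0, 1])
        )
        by_threshold = ["direct" if v < thr else "processed" for v in x]
        assert m.predict(x[:, None]) == by_threshold

    def test_full_lv_equals_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((14, 3))
        labels = ["direct" if v > 0 else "processed" for v in X[:, 0]]
        enc = ClassEncoding.from_labels(labels)
        m = fit_plsda(X, enc, 3)
        Xc = X - X.mean(axis=0)
        Yc = enc.Y - enc.Y.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        ols = Xc @ beta + enc.Y.mean(axis=0)
        np.testing.assert_allclose(m.predict_scores(X), ols, atol=1e-8)

    def test_prediction_invariant_to_sample_order(self):
        X, enc = two_class_data(seed=7)
        m = fit_plsda(X, enc, 2)
        perm = np.random.default_rng(0).permutation(len(enc.labels))
        assert m.predict(X[perm]) == [m.training_predictions[i] for i in perm]

    def test_constant_x_rejected(self):
        enc = ClassEncoding.from_labels(["direct", "processed"] * 3)
        with pytest.raises(ArithmeticError):
            fit_plsda(np.ones((6, 4)), enc, 1)


class TestCrossValidate:
    def test_separable_reaches_zero(self):
        X, enc = two_class_data(noise=0.05, seed=1)
        table, chosen = cross_validate(X, enc, max_lv=4)
        assert table["cv_misclassified"].min() == 0
        assert table.loc[chosen, "cv_misclassified"] <= 1

    def test_loo_runs_n_submodels(self):
        X, enc = two_class_data(n1=5, n2=6, seed=2)
        table, _ = cross_validate(X, enc, max_lv=2)
        # every sample held out exactly once: error counts bounded by n
        assert table["cv_misclassified"].max() <= 11
        assert np.all(table["cv_error"] == table["cv_misclassified"] / 11)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 10))
        errs = []
        for s in range(3):
            labels = list(rng.permutation(["direct"] * 15 + ["processed"] * 15))
            enc = ClassEncoding.from_labels(labels)
            table, chosen = cross_validate(X, enc, max_lv=3)
            errs.append(table["cv_error"].min())
        assert 0.3 <= np.mean(errs) <= 0.75

    def test_venetian_scheme(self):
        X, enc = two_class_data(noise=0.05, seed=3)
        table, chosen = cross_validate(
            X, enc, max_lv=3, scheme="venetian_k", n_folds=5
        )
        assert table["cv_misclassified"].min() == 0


class TestVip:
    def test_mean_squared_vip_is_one(self, sim, ds_interp):
        from ateem.core import unfold

        X = unfold(ds_interp).values
        enc = ClassEncoding.from_labels(sim.labels)
        for lv in (1, 3, 5):
            m = fit_plsda(X, enc, lv)
            assert np.mean(m.vip**2) == pytest.approx(1.0, rel=1e-10)
            assert (m.vip**2).sum() == pytest.approx(X.shape[1], rel=1e-10)

    def test_informative_variable_dominates(self):
        X, enc = two_class_data(p=20, gap=5.0, noise=0.2, seed=8)
        m = fit_plsda(X, enc, 2)
        assert np.argmax(m.vip) == 0 and m.vip[0] >= 1.0

    def test_vip_map_refolds_onto_wavelength_plane(self, sim, ds_interp):
        from ateem.core import unfold

        X = unfold(ds_interp)
        enc = ClassEncoding.from_labels(sim.labels)
        m = fit_plsda(X.values, enc, 4)
        vmap = vip_eem_map(m.vip, ds_interp.em_grid, ds_interp.ex_grid)
        assert vmap.intensity.shape == (64, 29)
        # round trip preserves the (em, ex) tagging of each variable
        j = ds_interp.em_grid.nearest_index(X.column_em[100])
        k = ds_interp.ex_grid.nearest_index(X.column_ex[100])
        assert vmap.intensity[j, k] == m.vip[100]

    def test_uniform_vector_gives_uniform_map(self):
        em = WavelengthGrid(np.array([310.0, 320.0, 330.0]))
        ex = WavelengthGrid(np.array([260.0, 270.0]))
        vmap = vip_eem_map(np.ones(6), em, ex)
        np.testing.assert_array_equal(vmap.intensity, np.ones((3, 2)))

    def test_vip_peaks_in_browning_footprint(self, sim, ds_interp):
        from ateem.core import unfold

        X = unfold(ds_interp)
        enc = ClassEncoding.from_labels(sim.labels)
        m = fit_plsda(X.values, enc, 4)
        # the browning fluorophore's 365 nm excitation / 470 nm emission
        # footprint is class-informative and must be flagged important,
        # while the signal-free long-wavelength region must not be
        foot = (
            (X.column_em >= 440) & (X.column_em <= 510)
            & (X.column_ex >= 345) & (X.column_ex <= 385)
        )
        assert m.vip[foot].mean() >= 1.0
        assert m.vip[foot].mean() > 10 * m.vip[X.column_em >= 530].mean()
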