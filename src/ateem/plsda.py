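"""Two-class PLS-DA with cross-validated model size and VIP importance.

PLS2 regression (NIPALS, via scikit-learn) of a two-column 0/1 dummy
class matrix Y on the mean-centered spectral block X. A sample is
assigned to the class whose predicted dummy column is largest.
Performance metrics follow the standard confusion-matrix definitions:

    sensitivity            = TP / (TP + FN)
    specificity            = TN / (TN + FP)
    misclassification err. = (FP + FN) / (TP + TN + FP + FN)

Because which class counts as "class 1" is a convention, the model
reports the metric pair for both classes. Variable importance in
projection (VIP) is normalised so the mean squared VIP equals 1;
variables with VIP close to or above 1 are conventionally important.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .core import EEM, SpectralMatrix, WavelengthGrid, refold
from .errors import ClassError, DimensionError, FormatError

__all__ = [
    "ClassEncoding",
    "ConfusionMatrix",
    "PLSDAModel",
    "fit_plsda",
    "cross_validate",
    "sensitivity",
    "specificity",
    "misclassification_error",
    "vip",
    "vip_eem_map",
]


@dataclass(frozen=True)
class ClassEncoding:
    """Ordered two-class dummy coding; column order fixed as given."""

    classes: tuple[str, str]
    labels: tuple[str, ...]

    @classmethod
    def from_labels(cls, labels, classes: tuple[str, str] | None = None):
        labels = tuple(str(x) for x in labels)
        present = list(pd.unique(np.asarray(labels)))
        if classes is None:
            if {"direct", "processed"} <= set(present):
                classes = ("direct", "processed")
            elif len(present) == 2:
                classes = (present[0], present[1])
            else:
                raise ClassError(f"need exactly two classes, got {present}")
        if set(present) - set(classes):
            raise ClassError(f"labels {present} outside classes {classes}")
        if len(set(present)) != 2:
            raise ClassError("both classes must be present")
        return cls(tuple(classes), labels)

    @property
    def Y(self) -> np.ndarray:
        """Sample x 2 dummy matrix; each row sums to 1."""
        y = np.zeros((len(self.labels), 2))
        for i, lab in enumerate(self.labels):
            y[i, self.classes.index(lab)] = 1.0
        return y

    def decode(self, Y_pred: np.ndarray) -> list[str]:
        """Class assignment by argmax over the two predicted dummy columns."""
        return [self.classes[j] for j in np.argmax(np.atleast_2d(Y_pred), axis=1)]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts for one choice of positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DimensionError("confusion counts must be nonnegative")
        if self.total < 1:
            raise DimensionError("confusion matrix must count at least 1 sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive_class) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive_class
        pos_p = y_pred == positive_class
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN): proportion of positive cases correctly identified."""
    if cm.tp + cm.fn == 0:
        raise DimensionError("sensitivity undefined: no positive cases")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP): proportion of negative cases correctly classified."""
    if cm.tn + cm.fp == 0:
        raise DimensionError("specificity undefined: no negative cases")
    return cm.tn / (cm.tn + cm.fp)


def misclassification_error(cm: ConfusionMatrix) -> float:
    """(FP + FN) / total: proportion of incorrectly classified samples."""
    return (cm.fp + cm.fn) / cm.total


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectralMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError("X must be a 2-D samples x variables matrix")
    if not np.all(np.isfinite(X)):
        raise FormatError("X contains missing values; fill before PLS-DA")
    return X


@dataclass
class PLSDAModel:
    """A fitted two-class PLS-DA model with VIP scores."""

    n_lv: int
    classes: tuple[str, str]
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    regression_coefficients: np.ndarray
    intercept: np.ndarray
    x_mean: np.ndarray
    vip: np.ndarray
    preprocessing: str
    scale: np.ndarray | None = None
    cv_table: pd.DataFrame | None = None
    training_predictions: list[str] = field(default_factory=list)

    def predict_scores(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if self.scale is not None:
            X = X / self.scale
        return (X - self.x_mean) @ self.regression_coefficients + self.intercept

    def predict(self, X) -> list[str]:
        return [
            self.classes[j] for j in np.argmax(self.predict_scores(X), axis=1)
        ]

    def confusion(self, labels, positive_class: str | None = None,
                  predictions=None) -> ConfusionMatrix:
        preds = self.training_predictions if predictions is None else predictions
        pos = positive_class or self.classes[0]
        return ConfusionMatrix.from_labels(labels, preds, pos)


def _vip_scores(pls: PLSRegression) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a)."""
    W = pls.x_weights_
    T = pls.x_scores_
    Q = pls.y_loadings_
    p, a = W.shape
    ssy = np.einsum("na,na->a", T, T) * np.einsum("ma,ma->a", Q, Q)
    if ssy.sum() <= 0:
        raise ArithmeticError("VIP undefined: model explains no Y variance")
    wn = W / np.linalg.norm(W, axis=0)
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())


def fit_plsda(
    X,
    encoding: ClassEncoding,
    n_lv: int,
    preprocessing: str = "mean_center",
) -> PLSDAModel:
    """Fit a PLS2 regression of the dummy class matrix on centered X."""
    X = _as_matrix(X)
    n, p = X.shape
    if len(encoding.labels) != n:
        raise DimensionError("one label per sample required")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise DimensionError(
            f"n_lv={n_lv} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ArithmeticError(
            "X is degenerate: every column is constant (zero variance)"
        )
    scale = None
    if preprocessing == "autoscale":
        if np.any(sd == 0):
            raise ArithmeticError(
                f"autoscale impossible: {int((sd == 0).sum())} constant columns"
            )
        scale = sd
        X = X / scale
    elif preprocessing != "mean_center":
        raise FormatError(f"unknown preprocessing '{preprocessing}'")
    Y = encoding.Y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when LVs exhaust Y rank
        pls = PLSRegression(n_components=n_lv, scale=False).fit(X, Y)
    coef = pls.coef_.T  # (p, 2), applies to centered X
    intercept = pls.intercept_
    model = PLSDAModel(
        n_lv=n_lv,
        classes=encoding.classes,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_,
        regression_coefficients=coef,
        intercept=intercept,
        x_mean=X.mean(axis=0),
        vip=_vip_scores(pls),
        preprocessing=preprocessing,
        scale=scale,
    )
    model.training_predictions = encoding.decode(pls.predict(X))
    return model


def _folds(n: int, labels, scheme: str, n_folds: int, seed):
    if scheme == "leave_one_out":
        return [np.array([i]) for i in range(n)]
    if scheme != "venetian_k":
        raise FormatError(f"unknown CV scheme '{scheme}'")
    labels = np.asarray(labels)
    folds = [np.arange(n)[f::n_folds] for f in range(n_folds)]
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        if len(np.unique(labels[train])) < 2:
            warnings.warn(
                "venetian fold left a single-class training set; "
                "falling back to class-stratified folds",
                stacklevel=3,
            )
            rng = np.random.default_rng(seed)
            order = np.concatenate(
                [rng.permutation(np.nonzero(labels == c)[0])
                 for c in pd.unique(labels)]
            )
            return [order[f::n_folds] for f in range(n_folds)]
    return folds


def cross_validate(
    X,
    encoding: ClassEncoding,
    max_lv: int,
    scheme: str = "leave_one_out",
    n_folds: int = 5,
    seed: int | None = None,
    preprocessing: str = "mean_center",
):
    """Cross-validated misclassification per LV count and the chosen size.

    The chosen number of latent variables is the smallest whose CV
    misclassification count is within one sample of the minimum (a
    parsimony rule). Returns ``(cv_table, chosen_n_lv)``.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if max_lv < 1:
        raise DimensionError("max_lv must be >= 1")
    max_lv = min(max_lv, n - 2, X.shape[1])
    labels = np.asarray(encoding.labels)
    folds = _folds(n, labels, scheme, n_folds, seed)
    errors = np.zeros(max_lv, dtype=int)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        enc_train = ClassEncoding(encoding.classes, tuple(labels[train_idx]))
        for lv in range(1, max_lv + 1):
            model = fit_plsda(X[train_idx], enc_train, lv, preprocessing)
            pred = model.predict(X[test_idx])
            errors[lv - 1] += int(np.sum(pred != labels[test_idx]))
    table = pd.DataFrame(
        {
            "n_lv": np.arange(1, max_lv + 1),
            "cv_misclassified": errors,
            "cv_error": errors / n,
        }
    ).set_index("n_lv")
    chosen = int(table.index[table["cv_misclassified"] <= errors.min() + 1][0])
    return table, chosen


def vip(model: PLSDAModel) -> np.ndarray:
    """Per-variable VIP scores of a fitted model (mean squared VIP = 1)."""
    return model.vip


def vip_eem_map(
    vip_vector: np.ndarray, em_grid: WavelengthGrid, ex_grid: WavelengthGrid
) -> EEM:
    """Refold an unfolded-EEM VIP vector onto the wavelength plane.

    Returns an :class:`~ateem.core.EEM` carrying the importance map so it
    can be written with :func:`~ateem.core.write_eem_csv` for plotting.
    """
    m = refold(np.asarray(vip_vector, float), em_grid, ex_grid)
    return EEM(ex_grid, em_grid, m, sample_id="vip_map")
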