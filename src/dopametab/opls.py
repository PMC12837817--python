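"""Orthogonal partial least squares discriminant analysis (OPLS-DA).

Two-class discriminant modelling for metabolomics matrices. Variation in X
that is uncorrelated with the class variable is removed by orthogonal
signal correction (NIPALS deflation), then a single predictive PLS
component is fitted on the filtered matrix. The model reports R²Y (class
variance explained), Q²Y (stratified cross-validated predictive ability),
per-feature VIP scores, correlations of each feature with the predictive
scores, and a label-permutation p-value for the class separation.

Conventions: features are mean-centred and unit-variance scaled internally;
the predictive scores are sign-fixed to correlate positively with the
treatment (positive) class; VIP is computed over the predictive component
only, so mean(VIP²) = 1 exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "OPLSDA",
    "fit_oplsda",
    "cross_validated_q2",
    "vip_scores",
    "predictive_correlations",
    "permutation_test",
]

_EPS = 1e-12


def _center_scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd < _EPS, 1.0, sd)
    return (x - mean) / sd, mean, sd


def _nipals_opls(xs: np.ndarray, yc: np.ndarray, n_ortho: int):
    """Core OSC deflation + single predictive PLS1 component.

    ``xs`` is the scaled matrix, ``yc`` the centred class variable.
    Returns (w, t, p, q, W_ortho, P_ortho, T_ortho) with the predictive
    weight w unit-norm and scores sign-fixed so that t·yc > 0.
    """
    x = xs.copy()
    w_orth, p_orth, t_orth = [], [], []
    for _ in range(n_ortho):
        w = x.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise ValueError("class variable carries no covariance with X")
        w /= nw
        t = x @ w
        p = x.T @ t / (t @ t)
        wo = p - (w @ p) * w
        nwo = np.linalg.norm(wo)
        if nwo < _EPS:
            raise ValueError(
                "no orthogonal variation left to remove; reduce n_orthogonal"
            )
        wo /= nwo
        to = x @ wo
        po = x.T @ to / (to @ to)
        x = x - np.outer(to, po)
        w_orth.append(wo)
        p_orth.append(po)
        t_orth.append(to)
    w = x.T @ yc
    nw = np.linalg.norm(w)
    if nw < _EPS:
        raise ValueError("class variable carries no covariance with X")
    w /= nw
    t = x @ w
    p = x.T @ t / (t @ t)
    if t @ yc < 0:  # sign convention: scores track the positive class
        w, t, p = -w, -t, -p
    q = yc @ t / (t @ t)
    return w, t, p, q, w_orth, p_orth, t_orth


class OPLSDA(BaseEstimator):
    """OPLS-DA with one predictive and ``n_orthogonal`` orthogonal components.

    Parameters
    ----------
    n_orthogonal
        Number of class-orthogonal components removed before the predictive
        fit. One matches the usual two-axis (P1 vs O1) score plot.
    positive_class
        Label treated as the treatment class (y encoded 1). Defaults to the
        lexicographically larger of the two labels.

    Attributes
    ----------
    weights_ : (n_features,) predictive weight vector (unit norm).
    scores_ : (n_samples,) predictive scores t of the training data.
    loadings_ : (n_features,) predictive loadings p.
    y_loading_ : scalar regression loading q of the centred class variable.
    ortho_weights_, ortho_loadings_ : (n_ortho, n_features).
    ortho_scores_ : (n_samples, n_ortho).
    r2y_ : fraction of class-variable variance explained.
    r2x_predictive_, r2x_ortho_ : explained X-variance fractions.
    vip_ : per-feature variable importance in projection; mean(vip_²) = 1.
    """

    def __init__(self, n_orthogonal: int = 1, positive_class=None):
        self.n_orthogonal = n_orthogonal
        self.positive_class = positive_class

    def fit(self, X, y):
        x = np.asarray(X, float)
        y = np.asarray(y)
        if x.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"OPLS-DA needs exactly 2 classes, got {classes.size}")
        if self.positive_class is None:
            pos = classes[1]
        else:
            pos = self.positive_class
            if pos not in classes:
                raise ValueError(f"positive_class {pos!r} not present in y")
        y01 = (y == pos).astype(float)
        if y01.sum() < 2 or (1 - y01).sum() < 2:
            raise ValueError("each class needs at least 2 samples")
        if self.n_orthogonal < 0:
            raise ValueError("n_orthogonal must be >= 0")
        xs, self.x_mean_, self.x_std_ = _center_scale(x)
        rank = np.linalg.matrix_rank(xs)
        if self.n_orthogonal >= rank:
            raise ValueError(
                f"n_orthogonal={self.n_orthogonal} >= rank(X)={rank}"
            )
        yc = y01 - y01.mean()
        w, t, p, q, wo, po, to = _nipals_opls(xs, yc, self.n_orthogonal)
        self.classes_ = np.array([c for c in classes if c != pos] + [pos])
        self.positive_class_ = pos
        self.y_mean_ = y01.mean()
        self.weights_ = w
        self.scores_ = t
        self.loadings_ = p
        self.y_loading_ = q
        n_feat = x.shape[1]
        self.ortho_weights_ = (
            np.array(wo) if wo else np.empty((0, n_feat))
        )
        self.ortho_loadings_ = (
            np.array(po) if po else np.empty((0, n_feat))
        )
        self.ortho_scores_ = (
            np.column_stack(to) if to else np.empty((x.shape[0], 0))
        )
        ssx = float((xs**2).sum())
        self.r2x_predictive_ = float((t @ t) * (p @ p) / ssx)
        self.r2x_ortho_ = np.array(
            [float((ti @ ti) * (pi @ pi) / ssx) for ti, pi in zip(to, po)]
        )
        resid = yc - t * q
        self.r2y_ = float(1.0 - (resid @ resid) / (yc @ yc))
        self.vip_ = np.sqrt(n_feat) * np.abs(w)
        self.n_features_in_ = n_feat
        self._xs_train = xs
        return self

    def _filter(self, xs: np.ndarray) -> np.ndarray:
        """Remove the fitted orthogonal components from a scaled matrix."""
        x = xs.copy()
        for wo, po in zip(self.ortho_weights_, self.ortho_loadings_):
            to = x @ wo
            x = x - np.outer(to, po)
        return x

    def transform(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Project new samples: returns (predictive scores, orthogonal scores)."""
        check_is_fitted(self, "weights_")
        xs = (np.asarray(X, float) - self.x_mean_) / self.x_std_
        t_ortho = np.empty((xs.shape[0], len(self.ortho_weights_)))
        x = xs.copy()
        for k, (wo, po) in enumerate(zip(self.ortho_weights_, self.ortho_loadings_)):
            to = x @ wo
            t_ortho[:, k] = to
            x = x - np.outer(to, po)
        return x @ self.weights_, t_ortho

    def decision_function(self, X) -> np.ndarray:
        """Continuous class prediction on the 0/1 encoding scale."""
        t, _ = self.transform(X)
        return t * self.y_loading_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        yhat = self.decision_function(X)
        neg = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(yhat >= 0.5, self.positive_class_, neg)

    def predictive_correlations(self, X=None) -> np.ndarray:
        """Pearson r between each scaled feature and the predictive scores."""
        check_is_fitted(self, "weights_")
        xs = (
            self._xs_train
            if X is None
            else (np.asarray(X, float) - self.x_mean_) / self.x_std_
        )
        t = self.scores_ if X is None else self.transform(X)[0]
        xc = xs - xs.mean(axis=0)
        tc = t - t.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (tc @ tc))
        zero = denom < _EPS
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance feature(s): correlation set to 0",
                stacklevel=2,
            )
        denom[zero] = 1.0
        r = (xc.T @ tc) / denom
        r[zero] = 0.0
        return r


def fit_oplsda(x, y, n_ortho: int = 1, positive_class=None) -> OPLSDA:
    """Functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(n_orthogonal=n_ortho, positive_class=positive_class).fit(x, y)


def vip_scores(model: OPLSDA) -> np.ndarray:
    """VIP over the predictive component: sqrt(n_features)·|w|."""
    check_is_fitted(model, "vip_")
    return model.vip_


def predictive_correlations(model: OPLSDA, x=None) -> np.ndarray:
    return model.predictive_correlations(x)


def _effective_folds(y01: np.ndarray, n_folds: int) -> int:
    minority = int(min(y01.sum(), (1 - y01).sum()))
    if n_folds > minority:
        warnings.warn(
            f"n_folds={n_folds} exceeds the minority class size; using {minority}",
            stacklevel=3,
        )
        return minority
    return n_folds


def cross_validated_q2(
    x,
    y,
    n_folds: int = 7,
    n_ortho: int = 1,
    random_state: int = 0,
    positive_class=None,
) -> float:
    """Q²Y: 1 − PRESS/TSS over stratified held-out class predictions.

    Every fold refits the whole model (scaling, orthogonal deflation,
    predictive component) on the training split only. Fold assignment is
    deterministic given ``random_state``. ``n_folds`` equal to the number
    of samples gives leave-one-out.
    """
    x = np.asarray(x, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("Q2 requires exactly 2 classes")
    pos = positive_class if positive_class is not None else classes[1]
    y01 = (y == pos).astype(float)
    if x.shape[0] == n_folds:  # leave-one-out: no stratification possible
        folds = [(np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))]
    else:
        nf = _effective_folds(y01, n_folds)
        if nf < 2:
            raise ValueError("need at least 2 folds (2 samples per class)")
        skf = StratifiedKFold(n_splits=nf, shuffle=True, random_state=random_state)
        folds = list(skf.split(x, y01))
    press = 0.0
    for train, test in folds:
        ytr = y01[train]
        if ytr.sum() < 1 or (1 - ytr).sum() < 1:
            raise ValueError("a CV fold lost an entire class")
        xs, mean, sd = _center_scale(x[train])
        yc = ytr - ytr.mean()
        w, t, p, q, wo, po, _ = _nipals_opls(xs, yc, n_ortho)
        xt = (x[test] - mean) / sd
        for wok, pok in zip(wo, po):
            xt = xt - np.outer(xt @ wok, pok)
        yhat = (xt @ w) * q + ytr.mean()
        press += float(((y01[test] - yhat) ** 2).sum())
    tss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / tss


def permutation_test(
    x,
    y,
    n_perm: int = 200,
    statistic: str = "q2y",
    n_ortho: int = 1,
    n_folds: int = 7,
    random_state: int = 0,
    positive_class=None,
) -> dict:
    """Label-permutation significance of the class separation.

    The class labels are permuted ``n_perm`` times (default 200); the model
    is refitted and the statistic (Q²Y by default, or R²Y) recomputed each
    time. The empirical p uses the add-one convention
    p = (1 + #{perm ≥ observed}) / (1 + n_perm), so the smallest attainable
    p with 200 permutations is 1/201; ties count against the model.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("q2y", "r2y"):
        raise ValueError("statistic must be 'q2y' or 'r2y'")
    x = np.asarray(x, float)
    y = np.asarray(y)
    rng = np.random.default_rng(random_state)

    def _stat(labels, seed):
        if statistic == "q2y":
            return cross_validated_q2(
                x, labels, n_folds=n_folds, n_ortho=n_ortho,
                random_state=seed, positive_class=positive_class,
            )
        return fit_oplsda(x, labels, n_ortho=n_ortho, positive_class=positive_class).r2y_

    observed = _stat(y, random_state)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _stat(rng.permutation(y), int(rng.integers(2**31 - 1)))
    p = (1.0 + int((null >= observed).sum())) / (1.0 + n_perm)
    return {
        "statistic": statistic,
        "observed": observed,
        "p_value": p,
        "n_perm": n_perm,
        "null": null,
    }
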