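"""Multivariate analysis: PCA, HCA, PLS-DA with VIP, ROC/AUC, subranges.

PLS-DA is implemented here as NIPALS PLS2 on column-centered (optionally
autoscaled) X against a centered one-hot class matrix Y, with per-component
X deflation.  It exposes the model quantities chemometricians report:

* ``R2Y`` -- fraction of Y variance explained in fit,
* ``Q2``  -- cross-validated 1 - PRESS/SS(Y),
* ``VIP`` -- variable importance in projection, with the algebraic identity
  sum(VIP^2) = number of features.

PCA and hierarchical clustering delegate to scikit-learn / scipy; ROC curves
to :func:`sklearn.metrics.roc_curve` (trapezoidal AUC, equal to the
pair-counting definition with ties counted one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA as _SKPCA
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# unsupervised
# ---------------------------------------------------------------------------

def pca(X, n_components: int):
    """Column-centered SVD decomposition.

    Returns ``(scores, loadings, explained_variance)`` with loadings as rows
    (components x features) and explained variances non-increasing.
    """
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.components_, model.explained_variance_


def hca(X, linkage_rule: str = "average") -> np.ndarray:
    """Agglomerative clustering on Euclidean distances (scipy linkage matrix)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("HCA needs at least 2 samples")
    return linkage(X, method=linkage_rule, metric="euclidean")


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def _one_hot(labels, classes=None):
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    Y = np.zeros((labels.size, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y, np.asarray(classes)


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS2 discriminant model."""

    W: np.ndarray  # X-weights (p x A), unit columns
    P: np.ndarray  # X-loadings (p x A)
    C: np.ndarray  # Y-loadings (k x A)
    T: np.ndarray  # training scores (n x A)
    B: np.ndarray  # regression coefficients, centered X -> centered Y
    classes_: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    feature_names: list | None
    r2y: float
    ssy_per_lv: np.ndarray  # Y variance captured per latent variable
    kept: np.ndarray  # mask of non-constant columns retained at fit time

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


class PLSDA:
    """PLS-DA estimator with an sklearn-like fit/predict surface.

    ``scale=True`` autoscales columns to unit variance, the sensible default
    for matrices mixing absorbance and wavenumber-shift units; pass False for
    pure spectral matrices.  Constant columns are dropped with a warning.
    """

    def __init__(self, n_components: int = 3, scale: bool = True, max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol
        self.model_: PLSDAModel | None = None

    def fit(self, X, y):
        feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        labels = np.asarray(y)
        if np.unique(labels).size < 2:
            raise ValueError("PLS-DA needs at least 2 classes")
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        kept = x_sd > 0
        if not kept.all():
            warnings.warn(f"dropping {int((~kept).sum())} constant feature column(s)")
        if not kept.any():
            raise ValueError("all feature columns are constant")
        x_scale = np.where(kept, x_sd, 1.0) if self.scale else np.ones(X.shape[1])
        Xc = ((X - x_mean) / x_scale)[:, kept]
        rank = np.linalg.matrix_rank(Xc)
        A = self.n_components
        if A > rank:
            raise ValueError(f"n_components={A} exceeds rank(X)={rank}")
        Y, classes = _one_hot(labels)
        y_mean = Y.mean(axis=0)
        Yc = Y - y_mean

        n, p = Xc.shape
        k = Yc.shape[1]
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        C = np.zeros((k, A))
        T = np.zeros((n, A))
        ssy = np.zeros(A)
        Xd, Yd = Xc.copy(), Yc.copy()
        for a in range(A):
            u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
            t_old = None
            for _ in range(self.max_iter):
                w = Xd.T @ u
                w /= np.linalg.norm(w)
                t = Xd @ w
                c = Yd.T @ t / (t @ t)
                u = Yd @ c / (c @ c)
                if t_old is not None and np.linalg.norm(t - t_old) < self.tol * np.linalg.norm(t):
                    break
                t_old = t
            p_a = Xd.T @ t / (t @ t)
            Xd = Xd - np.outer(t, p_a)
            Yd = Yd - np.outer(t, c)
            W[:, a], P[:, a], C[:, a], T[:, a] = w, p_a, c, t
            ssy[a] = (t @ t) * (c @ c)

        B = W @ np.linalg.solve(P.T @ W, C.T)
        Yhat = Xc @ B
        ss_tot = np.sum(Yc**2)
        r2y = 1.0 - np.sum((Yc - Yhat) ** 2) / ss_tot
        self.model_ = PLSDAModel(
            W=W, P=P, C=C, T=T, B=B, classes_=classes, x_mean=x_mean,
            x_scale=x_scale, y_mean=y_mean, feature_names=feature_names,
            r2y=float(r2y), ssy_per_lv=ssy, kept=kept,
        )
        return self

    def _check(self, X):
        m = self.model_
        if m is None:
            raise ValueError("model is not fitted")
        if isinstance(X, pd.DataFrame):
            if m.feature_names is not None:
                if set(X.columns) != set(m.feature_names):
                    raise ValueError("feature names do not match training")
                X = X[m.feature_names]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.shape[1] != m.x_mean.size:
            raise ValueError("feature dimension mismatch")
        return X, m

    def decision_function(self, X) -> np.ndarray:
        """Predicted (uncentered) class-membership matrix Y-hat."""
        X, m = self._check(X)
        Xc = ((X - m.x_mean) / m.x_scale)[:, m.kept]
        return Xc @ m.B + m.y_mean

    def predict(self, X):
        """Class label = argmax over Y-hat columns (ties -> class order)."""
        yhat = self.decision_function(X)
        return self.model_.classes_[np.argmax(yhat, axis=1)]


def plsda_fit(X, labels, n_components: int = 3, scale: bool = True) -> PLSDA:
    return PLSDA(n_components=n_components, scale=scale).fit(X, labels)


def plsda_predict(est: PLSDA, X):
    return est.predict(X), est.decision_function(X)


def vip_scores(est: PLSDA | PLSDAModel) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a).

    Satisfies sum_j VIP_j^2 = p (feature count) exactly; features dropped as
    constant at fit time report VIP 0.
    """
    m = est.model_ if isinstance(est, PLSDA) else est
    w2 = m.W**2  # columns already unit-norm
    p = m.W.shape[0]
    contrib = (w2 * m.ssy_per_lv).sum(axis=1) / m.ssy_per_lv.sum()
    vip = np.sqrt(p * contrib)
    full = np.zeros(m.kept.size)
    full[m.kept] = vip
    return full


def q2_cv(X, labels, n_components: int = 3, folds: int = 7, seed: int = 0, scale: bool = True) -> float:
    """Cross-validated predictive fraction Q2 = 1 - PRESS/SS(Y).

    PRESS accumulates squared one-hot prediction error over stratified
    held-out folds; SS(Y) is the total centered one-hot variance.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    Y, classes = _one_hot(labels)
    ss = np.sum((Y - Y.mean(axis=0)) ** 2)
    press = 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, labels):
        est = PLSDA(n_components=n_components, scale=scale).fit(X[tr], labels[tr])
        # predictions on the training-model class set, aligned to global classes
        yhat_local = est.decision_function(X[te])
        yhat = np.zeros((len(te), len(classes)))
        for j_local, c in enumerate(est.model_.classes_):
            yhat[:, list(classes).index(c)] = yhat_local[:, j_local]
        press += np.sum((Y[te] - yhat) ** 2)
    return float(1.0 - press / ss)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # true positive rate per threshold
    specificity: np.ndarray  # 1 - false positive rate
    auc: float


def roc_auc(scores, binary_labels) -> ROCResult:
    """ROC curve and trapezoidal AUC for a binary score.

    Equals the fraction of positive-negative pairs ranked correctly, ties
    counted one half.
    """
    y = np.asarray(binary_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def multiclass_roc(yhat: np.ndarray, labels, classes) -> dict:
    """One-vs-rest ROC per class from the class's Y-hat column."""
    labels = np.asarray(labels)
    return {
        c: roc_auc(yhat[:, j], (labels == c).astype(int))
        for j, c in enumerate(classes)
    }


# ---------------------------------------------------------------------------
# spectral subranges
# ---------------------------------------------------------------------------

#: Subranges examined for combined-data classification (cm^-1).
DEFAULT_SUBRANGES = ((2800.0, 3300.0), (1600.0, 1700.0), (1400.0, 1500.0), (1200.0, 1400.0))


def subrange_features(feature_matrix, refs, range_cm: tuple) -> pd.DataFrame:
    """Restrict a feature matrix to bands whose nominal centers fall in range."""
    lo, hi = range_cm
    keep_bands = {r.name for r in refs if lo <= r.nominal_center <= hi}
    if not keep_bands:
        raise ValueError(f"range [{lo}, {hi}] cm^-1 contains no reference bands")
    cols = [c for c in feature_matrix.values.columns if c.split(":")[0] in keep_bands]
    return feature_matrix.values[cols]


def subrange_classify(
    feature_matrix,
    refs,
    range_cm: tuple,
    labels=None,
    n_components: int = 3,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
):
    """Stratified-CV PLS-DA accuracy using only bands inside ``range_cm``."""
    from .ml_staging import cross_validate  # local import avoids a cycle

    X = subrange_features(feature_matrix, refs, range_cm)
    y = feature_matrix.labels["group"] if labels is None else labels
    n_comp = min(n_components, X.shape[1])  # few-band ranges support fewer LVs
    return cross_validate(
        X, np.asarray(y), method="PLS-DA", folds=folds, repeats=repeats,
        seed=seed, smote_inside=True, method_kwargs={"n_components": n_comp},
    )
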