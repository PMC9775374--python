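"""Stage classification: SMOTE balancing, classifier panel, repeated CV.

The staging task is 4-class within one cancer group (1 nonspecific symptom,
2 cancer, 3 postoperative, 4 control) and is heavily imbalanced, so SMOTE is
applied -- inside the training folds only, to avoid leaking synthetic copies
into held-out data.  The panel holds eight methods: the in-package
backpropagation (BP) network and PLS-DA, a least-squares one-hot classifier
(MVLR), and five scikit-learn baselines behind one train/predict contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .band_features import assemble_features
from .chemometrics import PLSDA, _one_hot


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

@dataclass
class SMOTEConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote(X, labels, config: SMOTEConfig | None = None, rng=None):
    """Oversample every minority class to the majority size.

    Each synthetic sample is ``x + u * (x_nn - x)`` for a random minority
    sample ``x``, one of its k nearest minority neighbors ``x_nn``
    (Euclidean), and ``u ~ Uniform(0, 1)``; so it lies on the segment between
    its parents.  k is clamped (with a warning) when a class is smaller than
    k + 1; a singleton class is an error.
    """
    config = config or SMOTEConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    out_X, out_y = [X], [labels]
    for c, n_c in zip(classes, counts):
        need = target - n_c
        if need == 0:
            continue
        if n_c < 2:
            raise ValueError(f"class {c!r} has a single sample; SMOTE needs >= 2")
        k = config.k_neighbors
        if k > n_c - 1:
            warnings.warn(f"class {c!r}: clamping k_neighbors from {k} to {n_c - 1}")
            k = n_c - 1
        Xc = X[labels == c]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the sample itself
        base = rng.integers(0, n_c, size=need)
        pick = rng.integers(1, k + 1, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        parents = Xc[idx[base, pick]]
        synth = Xc[base] + u[:, None] * (parents - Xc[base])
        out_X.append(synth)
        out_y.append(np.full(need, c, dtype=labels.dtype))
    return np.vstack(out_X), np.concatenate(out_y)


# ---------------------------------------------------------------------------
# BP neural network
# ---------------------------------------------------------------------------

class BPClassifier:
    """One-hidden-layer feed-forward softmax classifier (backpropagation).

    Full-batch gradient descent on the cross-entropy loss with tanh hidden
    units.  Inputs are expected standardized.  ``hidden_units`` defaults to
    twice the feature count; training stops early when the loss plateaus.
    """

    def __init__(
        self,
        hidden_units: int | None = None,
        epochs: int = 2000,
        learning_rate: float = 0.05,
        seed: int = 0,
        patience: int = 100,
        tol: float = 1e-7,
    ):
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.patience = patience
        self.tol = tol

    def _forward(self, X):
        H = np.tanh(X @ self.W1 + self.b1)
        Z = H @ self.W2 + self.b2
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        return H, E / E.sum(axis=1, keepdims=True)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y, self.classes_ = _one_hot(np.asarray(y))
        n, p = X.shape
        k = Y.shape[1]
        h = self.hidden_units or 2 * p
        rng = np.random.default_rng(self.seed)
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / p), size=(p, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(h, k))
        self.b2 = np.zeros(k)
        self.loss_curve_ = []
        best, stale = np.inf, 0
        for _ in range(self.epochs):
            if not (np.isfinite(self.W1).all() and np.isfinite(self.W2).all()):
                raise RuntimeError(
                    f"BP training diverged: non-finite weights after "
                    f"{len(self.loss_curve_)} epochs (lr={self.learning_rate})"
                )
            H, Phat = self._forward(X)
            loss = -np.mean(np.sum(Y * np.log(Phat + 1e-12), axis=1))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"BP training diverged: non-finite loss (lr={self.learning_rate})"
                )
            self.loss_curve_.append(float(loss))
            if loss < best - self.tol:
                best, stale = loss, 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
            G2 = (Phat - Y) / n
            dW2 = H.T @ G2
            db2 = G2.sum(axis=0)
            G1 = (G2 @ self.W2.T) * (1.0 - H**2)
            dW1 = X.T @ G1
            db1 = G1.sum(axis=0)
            lr = self.learning_rate
            self.W1 -= lr * dW1
            self.b1 -= lr * db1
            self.W2 -= lr * dW2
            self.b2 -= lr * db2
        return self

    def predict_proba(self, X):
        return self._forward(np.asarray(X, dtype=float))[1]

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def bp_train(X, labels, hidden_units=None, epochs=2000, learning_rate=0.05, seed=0) -> BPClassifier:
    return BPClassifier(hidden_units, epochs, learning_rate, seed).fit(X, labels)


# ---------------------------------------------------------------------------
# classifier panel
# ---------------------------------------------------------------------------

class MVLRClassifier:
    """Least-squares fit to one-hot Y; classify by argmax of the fit."""

    def fit(self, X, y):
        Y, self.classes_ = _one_hot(np.asarray(y))
        self._lm = LinearRegression().fit(np.asarray(X, dtype=float), Y)
        return self

    def predict(self, X):
        yhat = self._lm.predict(np.asarray(X, dtype=float))
        return self.classes_[np.argmax(yhat, axis=1)]


class _PLSDAClassifier:
    """Panel adapter: clamps the LV count to the available feature count."""

    def __init__(self, n_components=3, scale=True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        a = min(self.n_components, X.shape[1])
        self._est = PLSDA(n_components=a, scale=self.scale).fit(X, y)
        return self

    def predict(self, X):
        return self._est.predict(np.asarray(X, dtype=float))


def classifier_panel() -> dict:
    """Registry of the eight staging methods: name -> factory(seed, **kwargs)."""

    def bp(seed=0, **kw):
        return BPClassifier(seed=seed, **kw)

    def knn(seed=0, **kw):
        return KNeighborsClassifier(**{"n_neighbors": 5, **kw})

    def rf(seed=0, **kw):
        return RandomForestClassifier(**{"n_estimators": 100, "random_state": seed, **kw})

    def dt(seed=0, **kw):
        return DecisionTreeClassifier(random_state=seed, **kw)

    def logistic(seed=0, **kw):
        return LogisticRegression(**{"max_iter": 2000, **kw})

    def svm(seed=0, **kw):
        return SVC(**{"kernel": "rbf", "random_state": seed, **kw})

    def mvlr(seed=0, **kw):
        return MVLRClassifier()

    def plsda(seed=0, **kw):
        return _PLSDAClassifier(**kw)

    return {
        "BP": bp, "KNN": knn, "RF": rf, "DT": dt,
        "Logistic": logistic, "SVM": svm, "MVLR": mvlr, "PLS-DA": plsda,
    }


def make_classifier(method: str, seed: int = 0, **kwargs):
    panel = classifier_panel()
    if method not in panel:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(panel)}")
    return panel[method](seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Repeated stratified CV summary for one method/feature-set pairing."""

    method: str
    feature_mode: str
    accuracy: float  # mean over folds and repeats
    accuracy_sd: float  # sd over repeat means
    confusion: pd.DataFrame  # true x predicted counts over all held-out preds
    per_class: pd.DataFrame  # sensitivity and specificity per class
    folds: int
    repeats: int

    def __str__(self) -> str:
        mode = f" [{self.feature_mode}]" if self.feature_mode else ""
        return (
            f"{self.method}{mode} "
            f"accuracy {100*self.accuracy:.1f}% (+/-{100*self.accuracy_sd:.2f}), "
            f"{self.folds}-fold x {self.repeats}"
        )


def _sens_spec(confusion: pd.DataFrame) -> pd.DataFrame:
    total = confusion.to_numpy().sum()
    rows = []
    for c in confusion.index:
        tp = confusion.loc[c, c]
        fn = confusion.loc[c].sum() - tp
        fp = confusion[c].sum() - tp
        tn = total - tp - fn - fp
        rows.append(
            {
                "class": c,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def cross_validate(
    X,
    labels,
    method="BP",
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    smote_inside: bool = True,
    smote_k: int = 5,
    pca_variance: float | None = None,
    leak_preprocessing: bool = False,
    method_kwargs: dict | None = None,
    feature_mode: str = "",
) -> ClassificationReport:
    """Repeated stratified k-fold CV with in-fold standardization and SMOTE.

    Standardization, optional PCA reduction, and SMOTE are fit on the
    training folds only.  ``leak_preprocessing=True`` deliberately fits them
    on the full data before splitting (an ablation mode; it inflates accuracy
    on null data and exists so that the leakage regression test can detect
    the difference).  When the smallest class has fewer samples than
    ``folds``, the fold count is reduced with a warning.

    ``method`` is a panel name or a factory ``f(seed=..., **kwargs)``
    returning any object with fit/predict.
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    method_kwargs = method_kwargs or {}
    classes, counts = np.unique(labels, return_counts=True)
    min_class = counts.min()
    if min_class < folds:
        warnings.warn(f"smallest class has {min_class} samples; reducing folds to {min_class}")
        folds = int(min_class)
    if folds < 2:
        raise ValueError("folds must be >= 2 after class-size adjustment")

    conf = pd.DataFrame(0.0, index=classes, columns=classes)
    repeat_means = []
    fold_accs_all = []
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        fold_accs = []
        if leak_preprocessing:
            scaler_full = StandardScaler().fit(X)
            X_leak = scaler_full.transform(X)
            X_bal, y_bal = (
                smote(X_leak, labels, SMOTEConfig(smote_k), rng=np.random.default_rng(rep_seed))
                if smote_inside
                else (X_leak, labels)
            )
        for fold_i, (tr, te) in enumerate(skf.split(X, labels)):
            if leak_preprocessing:
                Xtr, ytr = X_bal, y_bal
                Xte, yte = X_leak[te], labels[te]
            else:
                scaler = StandardScaler().fit(X[tr])
                Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
                ytr, yte = labels[tr], labels[te]
                if smote_inside:
                    Xtr, ytr = smote(
                        Xtr, ytr, SMOTEConfig(smote_k),
                        rng=np.random.default_rng((rep_seed + fold_i) % 2**31),
                    )
            if pca_variance is not None:
                red = PCA(n_components=pca_variance, svd_solver="full").fit(Xtr)
                Xtr, Xte = red.transform(Xtr), red.transform(Xte)
            if callable(method):
                clf = method(seed=rep_seed, **method_kwargs)
            else:
                clf = make_classifier(method, seed=rep_seed, **method_kwargs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xtr, ytr)
                pred = clf.predict(Xte)
            fold_accs.append(float(np.mean(pred == yte)))
            for t, p in zip(yte, pred):
                conf.loc[t, p] += 1
        repeat_means.append(float(np.mean(fold_accs)))
        fold_accs_all.extend(fold_accs)
    return ClassificationReport(
        method=method if isinstance(method, str) else getattr(method, "__name__", "custom"),
        feature_mode=feature_mode,
        accuracy=float(np.mean(repeat_means)),
        accuracy_sd=float(np.std(repeat_means, ddof=1)) if repeats > 1 else 0.0,
        confusion=conf,
        per_class=_sens_spec(conf),
        folds=folds,
        repeats=repeats,
    )


# ---------------------------------------------------------------------------
# feature-set comparison
# ---------------------------------------------------------------------------

#: Feature-set vocabulary: (mode, source) pairs for assemble_features.
FEATURE_SETS = {
    "1D-raw": ("1D", "raw"),
    "2D-raw": ("2D", "raw"),
    "1D-sd": ("1D", "sd"),
    "2D-sd": ("2D", "sd"),
    "combined": ("combined", None),
}


def staging_cohort(cohort, group: str):
    """Samples for one group's 4-class staging task: its stages 1-3 + controls."""
    sub = cohort.subset(lambda m: m["group"] in (group, "Control"))
    if not any(s.meta["group"] == group for s in sub.spectra):
        raise ValueError(f"cohort has no samples for group {group!r}")
    return sub


def feature_matrix_for(cohort, feature_set: str, refs=None, config=None):
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; choose from {sorted(FEATURE_SETS)}")
    mode, source = FEATURE_SETS[feature_set]
    if mode == "combined":
        return assemble_features(cohort, mode="combined", refs=refs, config=config)
    return assemble_features(cohort, mode=mode, source=source, refs=refs, config=config)


def compare_feature_sets(
    cohort,
    group: str | None = None,
    methods: list | None = None,
    feature_sets: tuple = ("1D-sd", "2D-sd"),
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    refs=None,
    config=None,
    **cv_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Method x feature-set accuracy table plus per-cell confusion matrices.

    ``group=None`` runs the 4-group (LC/GC/CC/Control) task; a group name
    runs that group's 4-class staging task (labels = stage).  Returns
    ``(table, reports)`` with ``table`` holding "mean (sd)" percent strings
    and ``reports[(method, feature_set)]`` the full reports.
    """
    methods = methods or list(classifier_panel())
    sub = cohort if group is None else staging_cohort(cohort, group)
    label_col = "group" if group is None else "stage"
    if group is not None and not all("stage" in s.meta for s in sub.spectra):
        raise ValueError("staging task requires stage labels on every sample")
    table = pd.DataFrame(index=methods, columns=list(feature_sets), dtype=object)
    reports = {}
    for fs in feature_sets:
        fm = feature_matrix_for(sub, fs, refs=refs, config=config)
        y = fm.labels[label_col].to_numpy()
        for m in methods:
            rep = cross_validate(
                fm.values, y, method=m, folds=folds, repeats=repeats,
                seed=seed, feature_mode=fs, **cv_kwargs,
            )
            reports[(m, fs)] = rep
            table.loc[m, fs] = f"{100*rep.accuracy:.1f} (+/-{100*rep.accuracy_sd:.2f})"
    return table, reports
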