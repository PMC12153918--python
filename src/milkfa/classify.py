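"""Supervised re-prediction of cluster labels and membership probabilities.

Two model families re-predict the unsupervised cluster labels so that the
whole population (and any external population) can be scored without
re-clustering:

* PLS-DA — partial least squares regression of the one-hot class
  indicator on centered/scaled features, suited to the strong
  collinearity among FA traits; the component count is picked by
  cross-validated accuracy up to a maximum of 30.
* Random forest — 500 Gini-split trees with the per-split feature count
  tuned by cross-validation.  Membership probabilities are the
  proportions of trees voting for each cluster, which is what turns the
  hard cluster label into a continuous herd-monitoring signal.

Evaluation is stratified 10-fold cross-validation scoring every record
exactly once out-of-fold; performance is summarised by global accuracy
and Cohen's kappa on the pooled confusion matrix (predicted as rows).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "first_derivative",
    "PLSDAClassifier",
    "TunedRandomForestClassifier",
    "cross_validate",
    "predict_membership",
    "confusion_accuracy",
    "confusion_kappa",
]


def first_derivative(spectra) -> np.ndarray | pd.DataFrame:
    """Adjacent-difference transform along the spectral axis.

    Maps p points to p-1 differences ``x[i+1] - x[i]`` per record,
    removing any per-record baseline offset.
    """
    arr = np.asarray(spectra, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("spectra need at least 2 points per record")
    out = np.diff(arr, axis=1)
    if isinstance(spectra, pd.DataFrame):
        cols = [f"d{c}" for c in spectra.columns[1:]]
        return pd.DataFrame(out, columns=cols, index=spectra.index)
    return out


def _argmax_lowest(proba: np.ndarray, classes: np.ndarray) -> np.ndarray:
    # np.argmax returns the first maximum: the lowest class wins ties
    return classes[np.argmax(proba, axis=1)]


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS discriminant analysis on centered and scaled features.

    The one-hot class indicator is regressed by partial least squares;
    predicted indicator scores are clipped at zero and renormalized into
    row-stochastic membership probabilities.  When ``n_components`` is
    None it is chosen to maximize cross-validated accuracy over
    ``1..max_components``.
    """

    def __init__(
        self,
        n_components: int | None = None,
        max_components: int = 30,
        cv_folds: int = 10,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _fit_one(self, x: np.ndarray, y_onehot: np.ndarray, ncomp: int):
        scaler = StandardScaler().fit(x)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(scaler.transform(x), y_onehot)
        return scaler, pls

    def fit(self, X, y) -> "PLSDAClassifier":
        x = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if not np.isfinite(x).all():
            raise ValueError("features must be finite")
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        max_nc = min(self.max_components, x.shape[1], x.shape[0] - 1)
        if self.n_components is not None:
            ncomp = int(self.n_components)
        else:
            skf = StratifiedKFold(
                n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
            )
            folds = list(skf.split(x, y))
            best_nc, best_acc = 1, -1.0
            for nc in range(1, max_nc + 1):
                hits = 0
                for tr, te in folds:
                    scaler, pls = self._fit_one(x[tr], onehot[tr], nc)
                    pred = pls.predict(scaler.transform(x[te]))
                    hits += int(
                        (self.classes_[pred.argmax(axis=1)] == y[te]).sum()
                    )
                acc = hits / len(y)
                if acc > best_acc:
                    best_nc, best_acc = nc, acc
            ncomp = best_nc
            self.cv_accuracy_ = best_acc
        self.n_components_ = ncomp
        self.scaler_, self.pls_ = self._fit_one(x, onehot, ncomp)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "pls_")
        scores = self.pls_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))
        clipped = np.clip(scores, 0.0, None)
        totals = clipped.sum(axis=1, keepdims=True)
        # an all-non-positive score row carries no signal: fall back to uniform
        uniform = np.full_like(clipped, 1.0 / clipped.shape[1])
        return np.where(totals > 0, clipped / np.where(totals > 0, totals, 1.0), uniform)

    def predict(self, X) -> np.ndarray:
        return _argmax_lowest(self.predict_proba(X), self.classes_)


class TunedRandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest with CV-tuned per-split feature count and vote probabilities.

    500 trees, Gini splitting.  ``max_features`` is selected by
    cross-validated accuracy over ``max_features_grid`` (default: sqrt(p),
    p/3, p/2).  ``predict_proba`` returns tree-vote proportions rather
    than averaged leaf frequencies — each tree casts one vote and the
    membership probability of a cluster is the fraction of trees voting
    for it.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features_grid: tuple = ("sqrt", 1 / 3, 1 / 2),
        cv_folds: int = 10,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_features_grid = max_features_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _make(self, max_features):
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            criterion="gini",
            max_features=max_features,
            random_state=self.random_state,
            n_jobs=1,
        )

    def fit(self, X, y) -> "TunedRandomForestClassifier":
        x = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        grid = list(self.max_features_grid)
        if len(grid) > 1:
            skf = StratifiedKFold(
                n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
            )
            folds = list(skf.split(x, y))
            best_mf, best_acc = grid[0], -1.0
            for mf in grid:
                hits = 0
                for tr, te in folds:
                    model = self._make(mf).fit(x[tr], y[tr])
                    hits += int((model.predict(x[te]) == y[te]).sum())
                acc = hits / len(y)
                if acc > best_acc:
                    best_mf, best_acc = mf, acc
            self.max_features_ = best_mf
            self.cv_accuracy_ = best_acc
        else:
            self.max_features_ = grid[0]
        self.forest_ = self._make(self.max_features_).fit(x, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-class tree-vote proportions (rows sum to 1 exactly)."""
        check_is_fitted(self, "forest_")
        x = np.asarray(X, dtype=float)
        votes = np.zeros((x.shape[0], len(self.forest_.classes_)))
        rows = np.arange(x.shape[0])
        for tree in self.forest_.estimators_:
            # member trees predict encoded class indices into forest_.classes_
            enc = tree.predict(x).astype(int)
            votes[rows, enc] += 1.0
        return votes / len(self.forest_.estimators_)

    def predict(self, X) -> np.ndarray:
        return _argmax_lowest(self.predict_proba(X), self.classes_)


def predict_membership(model, features) -> tuple[pd.DataFrame, np.ndarray]:
    """Membership probability table and hard labels for a fitted model.

    The hard label is the argmax of the probability row, lowest class
    winning ties — always consistent with the probability table.
    """
    proba = model.predict_proba(np.asarray(features, dtype=float))
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-9):
        raise AssertionError("probability rows must sum to 1")
    index = features.index if isinstance(features, pd.DataFrame) else None
    table = pd.DataFrame(
        proba, columns=[f"p{c}" for c in model.classes_], index=index
    )
    return table, _argmax_lowest(proba, model.classes_)


def cross_validate(
    features,
    labels,
    model,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified k-fold CV scoring each record exactly once out-of-fold.

    Returns ``(pooled confusion matrix, per-fold metrics)``.  The pooled
    matrix has predicted clusters as rows and reference clusters as
    columns; per-fold metrics carry accuracy and kappa per fold plus the
    fold-averaged and pooled values are derivable from it.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} records, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    pooled = np.zeros((k, k), dtype=int)
    fold_rows = []
    for f, (tr, te) in enumerate(skf.split(x, y)):
        fitted = clone(model).fit(x[tr], y[tr])
        pred = fitted.predict(x[te])
        cm = np.zeros((k, k), dtype=int)
        for p, r in zip(pred, y[te]):
            cm[pos[p], pos[r]] += 1
        pooled += cm
        cm_df = pd.DataFrame(cm, index=classes, columns=classes)
        fold_rows.append(
            {
                "fold": f,
                "n": len(te),
                "accuracy": confusion_accuracy(cm_df),
                "kappa": confusion_kappa(cm_df),
            }
        )
    pooled_df = pd.DataFrame(pooled, index=classes, columns=classes)
    pooled_df.index.name = "predicted"
    pooled_df.columns.name = "reference"
    return pooled_df, pd.DataFrame(fold_rows)


def confusion_accuracy(cm) -> float:
    """Global accuracy: trace over total."""
    counts = np.asarray(cm, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(counts) / total)


def confusion_kappa(cm) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with marginal chance agreement."""
    counts = np.asarray(cm, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / total**2)
    if p_e == 1.0:
        raise ValueError("kappa undefined: chance agreement is 1 (single cell)")
    return float((p_o - p_e) / (1.0 - p_e))
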