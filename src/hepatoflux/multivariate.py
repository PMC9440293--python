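"""PLS-DA with VIP scores and cross-validated per-class AUROC.

Partial least squares discriminant analysis fits a PLS2 regression of the
autoscaled feature matrix X against a one-hot class matrix Y using the
NIPALS algorithm.  Feature relevance is summarized by Variable Importance
in Projection:

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

where SS_a is the Y-variance explained by component a; features with
VIP > 1 are flagged discriminative.  Model quality is assessed by
stratified k-fold cross-validation with pooled one-vs-rest AUROC per
class (a Mann-Whitney rank statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = ["PlsdaModel", "plsda_fit", "vip", "cross_validate"]

_NIPALS_TOL = 1e-10
_NIPALS_MAXITER = 500


@dataclass
class PlsdaModel:
    classes: list
    features: list[str]
    weights: np.ndarray  # p x A (unit-norm columns)
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # n_classes x A
    scores: np.ndarray  # n x A
    ss_y: np.ndarray  # Y-variance explained per component
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    vip_: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Predicted dummy-Y values (one column per class)."""
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        W, P, Q = self.weights, self.x_loadings, self.y_loadings
        B = W @ np.linalg.pinv(P.T @ W) @ Q.T
        return Xc @ B + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.array(self.classes, dtype=object)[np.argmax(scores, axis=1)]


def _dummy(y, classes) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(y, dtype=object) == c, j] = 1.0
    return Y


def plsda_fit(
    X,
    y,
    n_components: int = 2,
    feature_names: list[str] | None = None,
) -> PlsdaModel:
    """Fit a PLS-DA model by NIPALS PLS2 on autoscaled X and dummy Y.

    X is samples x features (array or DataFrame); y the class labels.
    Constant features are dropped with a warning; ``n_components`` is
    capped at the effective rank.  Deterministic: each component's NIPALS
    iteration starts from the Y column with maximal variance.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    n, p = X.shape
    feature_names = feature_names or [f"f{j}" for j in range(p)]

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant features")
        X = X[:, keep]
        feature_names = [f for f, k in zip(feature_names, keep) if k]
        sd = sd[keep]
        p = X.shape[1]
    x_mean = X.mean(axis=0)
    Xc = (X - x_mean) / sd

    Y = _dummy(y, classes)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    ss_y_total = (Yc**2).sum()

    max_comp = min(n_components, p, n - 1)
    if max_comp < n_components:
        warnings.warn(f"n_components reduced to {max_comp} (rank limit)")

    Xr, Yr = Xc.copy(), Yc.copy()
    Ws, Ps, Qs, Ts, SS = [], [], [], [], []
    for _ in range(max_comp):
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
        if np.allclose(Xr, 0) or np.allclose(u, 0):
            break
        t_old = None
        for _it in range(_NIPALS_MAXITER):
            w = Xr.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xr @ w
            q = Yr.T @ t / (t @ t)
            u = Yr @ q / (q @ q) if (q @ q) > 0 else t
            if t_old is not None and np.linalg.norm(t - t_old) < _NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        if nw == 0 or (t @ t) == 0:
            break
        p_load = Xr.T @ t / (t @ t)
        q = Yr.T @ t / (t @ t)
        before = (Yr**2).sum()
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, q)
        SS.append(before - (Yr**2).sum())
        Ws.append(w)
        Ps.append(p_load)
        Qs.append(q)
        Ts.append(t)
    if not Ws:
        raise ValueError("NIPALS failed to extract any component")
    model = PlsdaModel(
        classes=classes,
        features=feature_names,
        weights=np.column_stack(Ws),
        x_loadings=np.column_stack(Ps),
        y_loadings=np.column_stack(Qs),
        scores=np.column_stack(Ts),
        ss_y=np.array(SS),
        x_mean=x_mean,
        x_scale=sd,
        y_mean=y_mean,
    )
    model.vip_ = vip(model)
    _ = ss_y_total  # total Y variance; retained for diagnostics
    return model


def vip(model: PlsdaModel) -> np.ndarray:
    """Variable Importance in Projection per feature.

    Satisfies sum_j VIP_j^2 = p exactly.
    """
    W = model.weights
    p = W.shape[0]
    ss = model.ss_y
    if ss.sum() <= 0:
        return np.ones(p)
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


def cross_validate(
    X,
    y,
    n_components: int = 2,
    k: int = 7,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of a PLS-DA model.

    Each fold is fit on the training split and produces class decision
    scores for its test split; test-split scores are pooled across folds
    and a one-vs-rest AUROC is computed per class, together with the
    overall misclassification error.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y.tolist()))
    _, counts = np.unique(y.astype(str), return_counts=True)
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        warnings.warn(f"folds reduced to {k_eff} (smallest class size)")
    if k_eff < 2:
        raise ValueError("smallest class has fewer than 2 members")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    pooled = np.zeros((len(y), len(classes)))
    pred = np.empty(len(y), dtype=object)
    for train, test in skf.split(X, y.astype(str)):
        m = plsda_fit(X[train], y[train], n_components=n_components)
        sc = m.decision_scores(X[test])
        # align columns in case a training fold lost a class (guarded by
        # stratification, but cheap to be safe)
        for j, c in enumerate(classes):
            if c in m.classes:
                pooled[test, j] = sc[:, m.classes.index(c)]
        pred[test] = m.predict(X[test])
    auroc = {}
    for j, c in enumerate(classes):
        truth = (y == c).astype(int)
        auroc[c] = float(roc_auc_score(truth, pooled[:, j]))
    error = float(np.mean(pred != y))
    return {"auroc": auroc, "error": error, "folds": k_eff, "classes": classes}
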