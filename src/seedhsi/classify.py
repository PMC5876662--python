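"""Classification models for seed viability.

PLS-DA is partial least squares regression (PLS1, NIPALS) on the numeric
class codes 1 (viable) / 2 (non-viable); a continuous prediction below 1.5
maps to class 1, otherwise class 2 (the boundary itself goes to the upper
code). The number of latent variables is chosen by leave-one-out
classification accuracy on the calibration set: the smallest count
achieving the maximum accuracy wins.

The SVM is a soft-margin C-SVC with RBF kernel; (C, gamma) are tuned on the
standard coarse log2 grid by stratified 5-fold cross-validated accuracy,
ties resolving toward the smaller C and then the smaller gamma. Inputs are
standardised by calibration mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import check_labels

DECISION_THRESHOLD = 1.5


# ---------------------------------------------------------------------------
# PLS-DA

@dataclass
class PLSDAModel:
    n_latent: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    weights: np.ndarray      # W, bands x A
    loadings: np.ndarray     # P, bands x A
    y_loadings: np.ndarray   # q, A
    coef: np.ndarray         # regression vector in (scaled) band space
    scores: np.ndarray       # calibration T, n x A
    loo_accuracy: dict[int, float] = field(default_factory=dict)
    decision_threshold: float = DECISION_THRESHOLD

    @property
    def n_bands(self) -> int:
        return self.x_mean.size


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_comp: int):
    """PLS1 NIPALS on centred data. Returns W, P, q, T and the regression
    vectors for every component count 1..n_comp (columns of B)."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    q = np.zeros(n_comp)
    T = np.zeros((n, n_comp))
    a_eff = 0
    for a in range(n_comp):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-12:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= 1e-12:
            break
        p_a = X.T @ t / tt
        q_a = y @ t / tt
        X -= np.outer(t, p_a)
        y -= q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        a_eff = a + 1
    W, P, q, T = W[:, :a_eff], P[:, :a_eff], q[:a_eff], T[:, :a_eff]
    # B_k = W (P'W)^-1 q for each truncation k, built incrementally:
    B = np.zeros((p, a_eff))
    if a_eff:
        PtW = P.T @ W  # upper triangular with unit-ish structure
        for k in range(1, a_eff + 1):
            bk = W[:, :k] @ np.linalg.solve(PtW[:k, :k], q[:k])
            B[:, k - 1] = bk
    return W, P, q, T, B


def fit_plsda(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    max_lv: int = 20,
    scale: bool = False,
) -> PLSDAModel:
    """Fit PLS-DA with leave-one-out latent-variable selection."""
    X = np.asarray(X_cal, dtype=float)
    y = check_labels(y_cal).astype(float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("PLS-DA needs both classes in the calibration set")
    if counts.min() < 2:
        raise ValueError("PLS-DA needs at least 2 samples per class")
    n, p = X.shape
    cap = min(max_lv, n - 2, p)  # n-2: one left out, one lost to centring
    if cap < 1:
        raise ValueError("not enough samples for leave-one-out LV selection")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    Xs = (X - x_mean) / x_sd

    # leave-one-out predictions for every candidate LV count in one pass
    hits = np.zeros(cap, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi = Xs[keep]
        yi = y[keep]
        mi = Xi.mean(axis=0)
        *_, B = _nipals_pls1(Xi - mi, yi - yi.mean(), cap)
        a_eff = B.shape[1]
        if a_eff == 0:
            continue
        preds = (Xs[i] - mi) @ B + yi.mean()
        labels = np.where(preds < DECISION_THRESHOLD, 1, 2)
        hits[:a_eff] += labels == int(y[i])
        if a_eff < cap:  # rank exhausted: higher counts behave like a_eff
            hits[a_eff:] += labels[-1] == int(y[i])
    acc = hits / n
    n_latent = int(np.argmax(acc)) + 1  # argmax takes the first (smallest) maximiser

    W, P, q, T, B = _nipals_pls1(Xs - Xs.mean(axis=0), y - y.mean(), n_latent)
    return PLSDAModel(
        n_latent=min(n_latent, B.shape[1]),
        x_mean=x_mean, x_sd=x_sd, y_mean=float(y.mean()),
        weights=W, loadings=P, y_loadings=q,
        coef=B[:, -1] if B.size else np.zeros(p),
        scores=T,
        loo_accuracy={k + 1: float(a) for k, a in enumerate(acc)},
    )


def decision_function_plsda(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_bands:
        raise ValueError(
            f"band mismatch: model expects {model.n_bands} bands, got {X.shape[1]}"
        )
    return (X - model.x_mean) / model.x_sd @ model.coef + model.y_mean


def predict_plsda(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Continuous prediction thresholded at 1.5; returns codes {1, 2}."""
    yhat = decision_function_plsda(model, X)
    return np.where(yhat < model.decision_threshold, 1, 2)


# ---------------------------------------------------------------------------
# SVM

@dataclass
class SVMSpec:
    C_grid: np.ndarray = field(default_factory=lambda: 2.0 ** np.arange(-5, 16, 2, dtype=float))
    gamma_grid: np.ndarray = field(default_factory=lambda: 2.0 ** np.arange(-15, 4, 2, dtype=float))
    cv_folds: int = 5
    standardize: bool = True


@dataclass
class SVMModel:
    estimator: SVC
    x_mean: np.ndarray
    x_sd: np.ndarray
    chosen_C: float
    chosen_gamma: float
    cv_accuracy: float

    @property
    def n_bands(self) -> int:
        return self.x_mean.size


def fit_svm(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    spec: SVMSpec | None = None,
    rng_seed: int = 0,
) -> SVMModel:
    """Grid-search C-SVC (RBF) with stratified 5-fold CV accuracy."""
    spec = SVMSpec() if spec is None else spec
    X = np.asarray(X_cal, dtype=float)
    y = check_labels(y_cal)
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2:
        raise ValueError("SVM needs both classes in the calibration set")
    if counts.min() < spec.cv_folds:
        raise ValueError(
            f"each class needs at least {spec.cv_folds} samples for {spec.cv_folds}-fold CV"
        )
    if spec.standardize:
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0, ddof=1)
        x_sd = np.where(x_sd == 0, 1.0, x_sd)
    else:
        x_mean = np.zeros(X.shape[1])
        x_sd = np.ones(X.shape[1])
    Xs = (X - x_mean) / x_sd

    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=rng_seed)
    splits = list(skf.split(Xs, y))
    best_acc, best_C, best_gamma = -1.0, None, None
    for C in spec.C_grid:          # ascending C, then ascending gamma:
        for gamma in spec.gamma_grid:  # strict '>' keeps the smallest tie winner
            hits = 0
            for tr, va in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(Xs[tr], y[tr])
                hits += int((clf.predict(Xs[va]) == y[va]).sum())
            acc = hits / len(y)
            if acc > best_acc:
                best_acc, best_C, best_gamma = acc, float(C), float(gamma)
    final = SVC(C=best_C, gamma=best_gamma, kernel="rbf")
    final.fit(Xs, y)
    return SVMModel(
        estimator=final, x_mean=x_mean, x_sd=x_sd,
        chosen_C=best_C, chosen_gamma=best_gamma, cv_accuracy=best_acc,
    )


def predict_svm(model: SVMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0, dtype=int)
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_bands:
        raise ValueError(
            f"band mismatch: model expects {model.n_bands} bands, got {X.shape[1]}"
        )
    return model.estimator.predict((X - model.x_mean) / model.x_sd).astype(int)
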