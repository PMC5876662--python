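"""Successive projections algorithm (SPA) for wavelength selection.

SPA is a forward selector built to minimise collinearity: starting from a
seed band, each step projects every unselected column of the (mean-centred)
calibration spectra matrix onto the orthogonal complement of the span of
the already-selected columns and appends the column of maximum projected
norm. Chains are grown from every starting band; each candidate subset
(start, size) is scored by the cross-validated RMSE of a multiple linear
regression of the numeric class code (1 = viable, 2 = non-viable) on the
selected columns; the global RMSE minimiser wins. A final elimination pass
ranks the winning subset's variables by absolute standardised regression
coefficient and keeps the shortest prefix whose RMSE is within one standard
error of the best prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, train_test_split

_NEGLIGIBLE = 1e-12


@dataclass
class SPAResult:
    chains: dict[int, list[int]]
    rmse_table: dict[tuple[int, int], float]
    selected_indices: list[int]
    selected_wavelengths: np.ndarray
    best_start: int = -1
    best_k: int = -1
    best_rmse: float = np.nan
    eliminated: list[int] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)


def spa_chain(X: np.ndarray, start: int, k_max: int) -> list[int]:
    """Grow one projection chain of up to ``k_max`` mutually well-conditioned
    columns, beginning at column ``start``.

    ``X`` must be column mean-centred. Columns whose orthogonal projection
    is numerically zero (e.g. duplicates of selected columns) are never
    selected; the chain stops early if no informative column remains, so
    selected columns are always linearly independent.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    bound = min(n - 1, p)
    if not (1 <= k_max <= bound):
        raise ValueError(
            f"k_max must be within [1, {bound}] (min(n_samples - 1, n_bands) rank bound), "
            f"got {k_max}"
        )
    if not (0 <= start < p):
        raise ValueError(f"start column {start} outside [0, {p})")

    R = X.copy()  # residuals of every column against the selected span
    norms0 = np.einsum("ij,ij->j", X, X)
    chain = [start]
    for _ in range(k_max - 1):
        sel = R[:, chain[-1]].copy()
        ss = sel @ sel
        if ss <= _NEGLIGIBLE:
            break
        # deflate all columns by their component along the newest direction
        R -= np.outer(sel, (sel @ R) / ss)
        norms = np.einsum("ij,ij->j", R, R)
        norms[chain] = -np.inf
        # relative tolerance guards duplicated/collinear columns
        norms[norms <= _NEGLIGIBLE * np.maximum(norms0, 1.0)] = -np.inf
        j = int(np.argmax(norms))
        if norms[j] == -np.inf:
            break
        chain.append(j)
    return chain


def evaluate_subset(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    indices,
) -> float:
    """RMSE on validation rows of an intercept-plus-selected-columns MLR fit
    on calibration rows. An empty index list scores the intercept-only
    model (calibration mean)."""
    indices = list(indices)
    if len(set(indices)) != len(indices):
        raise ValueError("indices must be distinct")
    y_cal = np.asarray(y_cal, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if not indices:
        pred = np.full(y_val.shape, y_cal.mean())
        return float(np.sqrt(np.mean((y_val - pred) ** 2)))
    A = np.column_stack([np.ones(len(y_cal)), X_cal[:, indices]])
    coef, _, rank, _ = np.linalg.lstsq(A, y_cal, rcond=None)
    if rank < A.shape[1]:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {A.shape[1]} columns (intercept + subset)"
        )
    Av = np.column_stack([np.ones(len(y_val)), X_val[:, indices]])
    pred = Av @ coef
    return float(np.sqrt(np.mean((y_val - pred) ** 2)))


def _cv_splits(n: int, validation: str, rng_seed: int):
    if validation == "5-fold":
        kf = KFold(n_splits=5, shuffle=True, random_state=rng_seed)
        return list(kf.split(np.arange(n)))
    if validation == "split":
        tr, va = train_test_split(np.arange(n), test_size=0.3, random_state=rng_seed)
        return [(tr, va)]
    raise ValueError("validation must be '5-fold' or 'split'")


def _cv_rmse(X, y, indices, splits) -> tuple[float, float]:
    """Pooled CV RMSE and its between-fold standard error."""
    fold_rmse = []
    sq_sum = 0.0
    n_val = 0
    for tr, va in splits:
        r = evaluate_subset(X[tr], y[tr], X[va], y[va], indices)
        fold_rmse.append(r)
        sq_sum += r * r * len(va)
        n_val += len(va)
    pooled = float(np.sqrt(sq_sum / n_val))
    se = float(np.std(fold_rmse, ddof=1) / np.sqrt(len(fold_rmse))) if len(fold_rmse) > 1 else 0.0
    return pooled, se


def spa_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    k_min: int = 5,
    k_max: int | None = None,
    validation: str = "5-fold",
    rng_seed: int = 0,
    wavelengths: np.ndarray | None = None,
    eliminate: bool = True,
) -> SPAResult:
    """Run the full three-step SPA on a calibration set.

    ``k_max`` defaults to min(30, n_samples // 4), capped by the rank bound.
    Deterministic given the inputs and ``rng_seed`` (which fixes the CV
    folds). Ties in the RMSE table resolve toward the smaller subset, then
    the smaller starting band.
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float)
    n, p = X.shape
    bound = min(n - 1, p)
    if k_max is None:
        k_max = min(30, max(n // 4, 1), bound)
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    if k_max > bound:
        raise ValueError(f"k_max {k_max} exceeds the rank bound {bound}")

    Xc = X - X.mean(axis=0)
    splits = _cv_splits(n, validation, rng_seed)

    chains: dict[int, list[int]] = {}
    rmse_table: dict[tuple[int, int], float] = {}
    best = (np.inf, -1, -1)  # (rmse, k, start)
    for start in range(p):
        chain = spa_chain(Xc, start, k_max)
        chains[start] = chain
        for k in range(k_min, len(chain) + 1):
            rmse, _ = _cv_rmse(X, y, chain[:k], splits)
            rmse_table[(start, k)] = rmse
            if (rmse, k, start) < best:
                best = (rmse, k, start)
    if best[1] < 0:
        raise ValueError("no candidate subset satisfied k_min (chains too short)")
    best_rmse, best_k, best_start = best
    selected = list(chains[best_start][:best_k])
    eliminated: list[int] = []

    if eliminate and len(selected) > k_min:
        ranked = _rank_by_relevance(X, y, selected)
        prefix_scores = []
        for k in range(k_min, len(ranked) + 1):
            prefix_scores.append((_cv_rmse(X, y, ranked[:k], splits), k))
        (min_rmse, min_se), _ = min(prefix_scores, key=lambda t: t[0][0])
        for (rmse, _se), k in prefix_scores:
            if rmse <= min_rmse + min_se:
                kept = ranked[:k]
                eliminated = [i for i in selected if i not in kept]
                selected = kept
                best_rmse, _ = _cv_rmse(X, y, selected, splits)
                break

    wl = np.asarray(wavelengths, dtype=float) if wavelengths is not None else np.arange(p, dtype=float)
    order = list(selected)
    return SPAResult(
        chains=chains,
        rmse_table=rmse_table,
        selected_indices=order,
        selected_wavelengths=wl[order],
        best_start=best_start,
        best_k=best_k,
        best_rmse=best_rmse,
        eliminated=eliminated,
    )


def _rank_by_relevance(X: np.ndarray, y: np.ndarray, indices: list[int]) -> list[int]:
    """Order ``indices`` by decreasing |standardised MLR coefficient|."""
    A = np.column_stack([np.ones(len(y)), X[:, indices]])
    coef, _, _, _ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
    scale = X[:, indices].std(axis=0, ddof=1)
    relevance = np.abs(coef[1:]) * scale
    order = np.argsort(-relevance, kind="stable")
    return [indices[i] for i in order]
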