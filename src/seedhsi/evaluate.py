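"""Viability-oriented evaluation: confusion bookkeeping, the four reported
metrics, confusion-matrix reconstruction from printed percentages, and the
experiment runner.

With class 1 = germinating, the confusion cells are G (germinating
predicted correctly), NG (non-germinating predicted correctly), Gr
(germinating called non-germinating) and NGr (non-germinating called
germinating). The four metrics:

    overall accuracy          = (G + NG) / (G + NG + Gr + NGr)
    viability accuracy        = G / (G + Gr)            (recall)
    final germination percent = G / (G + NGr)           (precision)
    F-measure                 = 2 * recall * precision / (recall + precision)

All percentages are reported rounded half-up to one decimal; full precision
is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd

from .classify import (
    SVMSpec,
    fit_plsda,
    fit_svm,
    predict_plsda,
    predict_svm,
)
from .core import NONVIABLE, VIABLE, SpectralDataset, check_labels
from .datasets import TABLE1_CONFIGS, MixtureConfig, apply_mixture_config, build_dataset
from .preprocess import PreprocessSpec, apply_preprocess
from .spa import spa_select
from .synthetic import Population


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 0.05 -> 0.1), as used for all reported
    percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    G: int
    NG: int
    Gr: int
    NGr: int

    def __post_init__(self) -> None:
        if min(self.G, self.NG, self.Gr, self.NGr) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_viable(self) -> int:
        return self.G + self.Gr

    @property
    def n_nonviable(self) -> int:
        return self.NG + self.NGr

    @property
    def total(self) -> int:
        return self.n_viable + self.n_nonviable


@dataclass(frozen=True)
class MetricsReport:
    overall_accuracy: float | None
    viability_accuracy: float | None
    final_germination: float | None
    f_measure: float | None

    def rounded(self) -> dict[str, float | str]:
        return {
            k: ("undefined" if v is None else round_half_up(v))
            for k, v in self.__dict__.items()
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count the four confusion cells; codes must be in {1, 2}."""
    yt = check_labels(y_true)
    yp = check_labels(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        G=int(np.sum((yt == VIABLE) & (yp == VIABLE))),
        NG=int(np.sum((yt == NONVIABLE) & (yp == NONVIABLE))),
        Gr=int(np.sum((yt == VIABLE) & (yp == NONVIABLE))),
        NGr=int(np.sum((yt == NONVIABLE) & (yp == VIABLE))),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The four metrics in percent; a zero denominator yields None
    ("undefined"), never 0."""
    acc = 100.0 * (c.G + c.NG) / c.total if c.total else None
    rec = 100.0 * c.G / c.n_viable if c.n_viable else None
    prec = 100.0 * c.G / (c.G + c.NGr) if (c.G + c.NGr) else None
    if rec is None or prec is None or (rec + prec) == 0:
        f = None
    else:
        f = 2.0 * rec * prec / (rec + prec)
    return MetricsReport(acc, rec, prec, f)


def f_measure(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision (percent in, percent out,
    one-decimal half-up reporting)."""
    if recall + precision <= 0:
        raise ValueError("F-measure undefined: recall + precision must be > 0")
    return round_half_up(2.0 * recall * precision / (recall + precision))


def initial_germination(n_viable: int, n_nonviable: int) -> float:
    """Germination percentage of a seed lot before any screening."""
    if n_viable + n_nonviable == 0:
        raise ValueError("empty lot")
    return round_half_up(100.0 * n_viable / (n_viable + n_nonviable))


def reconstruct_confusion(
    n_viable: int,
    n_nonviable: int,
    recall: float,
    precision: float,
    accuracy: float | None = None,
) -> list[ConfusionCounts]:
    """Exhaustively enumerate integer confusion matrices consistent with
    one-decimal-rounded recall/precision (and optionally accuracy) for a lot
    of ``n_viable`` + ``n_nonviable`` seeds.

    Returns every consistent matrix (more than one element means the
    percentages are ambiguous); raises if none exists.
    """
    if n_viable <= 0 or n_nonviable <= 0:
        raise ValueError("counts must be positive")
    out = []
    for G in range(n_viable + 1):
        if round_half_up(100.0 * G / n_viable) != round_half_up(recall):
            continue
        for NGr in range(n_nonviable + 1):
            if G + NGr == 0:
                continue
            if round_half_up(100.0 * G / (G + NGr)) != round_half_up(precision):
                continue
            c = ConfusionCounts(G=G, NG=n_nonviable - NGr, Gr=n_viable - G, NGr=NGr)
            if accuracy is not None:
                got = 100.0 * (c.G + c.NG) / c.total
                if round_half_up(got) != round_half_up(accuracy):
                    continue
            out.append(c)
    if not out:
        raise ValueError(
            f"no integer confusion matrix on a {n_viable}+{n_nonviable} lot matches "
            f"recall {recall}, precision {precision}"
            + (f", accuracy {accuracy}" if accuracy is not None else "")
        )
    return out


# ---------------------------------------------------------------------------
# Experiment runner


@dataclass
class ExperimentConfig:
    """Declarative grid over dataset kinds x pre-processing x selector x
    model, evaluated calibration (resubstitution) and prediction."""

    kinds: tuple[str, ...] = ("ventral", "reverse", "mean", "mixture")
    methods: tuple[str, ...] = ("raw", "snv", "msc", "sg")
    selectors: tuple[bool, ...] = (False, True)
    models: tuple[str, ...] = ("plsda", "svm")
    k_min: int = 5
    k_max: int | None = None
    max_lv: int = 20
    rng_seed: int = 0
    mixture_config: MixtureConfig = field(default_factory=MixtureConfig)

    def __post_init__(self) -> None:
        bad = set(self.models) - {"plsda", "svm"}
        if bad:
            raise ValueError(f"unknown models {sorted(bad)}")


def _r(value: float | None) -> float:
    # undefined metrics (zero denominator) surface as NaN in report tables
    return np.nan if value is None else round_half_up(value)


def _fit_predict(model_name, X_cal, y_cal, X_pred, max_lv, rng_seed):
    if model_name == "plsda":
        m = fit_plsda(X_cal, y_cal, max_lv=max_lv)
        return predict_plsda(m, X_cal), predict_plsda(m, X_pred), m
    m = fit_svm(X_cal, y_cal, SVMSpec(), rng_seed=rng_seed)
    return predict_svm(m, X_cal), predict_svm(m, X_pred), m


def evaluate_combination(
    dataset: SpectralDataset,
    method: str,
    use_selector: bool,
    model_name: str,
    k_min: int = 5,
    k_max: int | None = None,
    max_lv: int = 20,
    rng_seed: int = 0,
) -> dict:
    """Fit one (pre-processing, selector, model) combination on a dataset's
    calibration rows and score its prediction rows."""
    ds = apply_preprocess(dataset, PreprocessSpec(method=method))
    wavelengths = ds.wavelengths
    if use_selector:
        sel = spa_select(
            ds.X_cal, ds.y_cal, k_min=k_min, k_max=k_max,
            rng_seed=rng_seed, wavelengths=wavelengths,
        )
        cols = sel.selected_indices
        selected_nm = sel.selected_wavelengths
    else:
        cols = list(range(ds.X.shape[1]))
        selected_nm = wavelengths
    yhat_cal, yhat_pred, _ = _fit_predict(
        model_name, ds.X_cal[:, cols], ds.y_cal, ds.X_pred[:, cols], max_lv, rng_seed
    )
    cal_m = metrics(confusion(ds.y_cal, yhat_cal))
    pred_m = metrics(confusion(ds.y_pred, yhat_pred))
    return {
        "dataset": dataset.kind,
        "preprocess": method.upper() if method != "raw" else "RAW",
        "n_wavelengths": len(cols),
        "selector": "SPA" if use_selector else "full",
        "model": {"plsda": "PLS-DA", "svm": "SVM"}[model_name],
        "calibration_accuracy": _r(cal_m.overall_accuracy),
        "prediction_accuracy": _r(pred_m.overall_accuracy),
        "viability_accuracy": _r(pred_m.viability_accuracy),
        "final_germination": _r(pred_m.final_germination),
        "f_measure": _r(pred_m.f_measure),
        "selected_nm": " ".join(f"{w:.0f}" for w in np.asarray(selected_nm)),
    }


def run_experiment(population: Population, config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Evaluate the full combination grid on one simulated population.

    With the default grid this emits 4 datasets x 4 pre-processing methods
    x 2 selector settings x 2 models = 64 rows, mirroring the columns of
    the study's best-results table.
    """
    config = ExperimentConfig() if config is None else config
    rows = []
    for kind in config.kinds:
        ds = build_dataset(population, kind, mixture_config=config.mixture_config)
        for method in config.methods:
            for use_selector in config.selectors:
                for model_name in config.models:
                    rows.append(
                        evaluate_combination(
                            ds, method, use_selector, model_name,
                            k_min=config.k_min, k_max=config.k_max,
                            max_lv=config.max_lv, rng_seed=config.rng_seed,
                        )
                    )
    return pd.DataFrame(rows)


def run_mixture_proportions(
    population: Population,
    method: str = "snv",
    model_name: str = "plsda",
    use_selector: bool = True,
    configs: Iterable[tuple[int, int]] = TABLE1_CONFIGS,
    k_min: int = 5,
    k_max: int | None = None,
    max_lv: int = 20,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Train one model on the mixture calibration set, then score prediction
    sets of varying ventral/reverse proportions (one row per configuration;
    the calibration column is constant because the model is shared)."""
    full = build_dataset(population, "mixture", mixture_config="both-sides")
    ds = apply_preprocess(full, PreprocessSpec(method=method))
    if use_selector:
        sel = spa_select(ds.X_cal, ds.y_cal, k_min=k_min, k_max=k_max,
                         rng_seed=rng_seed, wavelengths=ds.wavelengths)
        cols = sel.selected_indices
    else:
        cols = list(range(ds.X.shape[1]))
    yhat_cal, _, model = _fit_predict(model_name, ds.X_cal[:, cols], ds.y_cal,
                                      ds.X_cal[:, cols], max_lv, rng_seed)
    cal_acc = _r(metrics(confusion(ds.y_cal, yhat_cal)).overall_accuracy)
    rows = []
    for i, (n_v, n_r) in enumerate(configs, start=1):
        sub = apply_mixture_config(ds, MixtureConfig(n_v, n_r, rng_seed))
        Xp = sub.X_pred[:, cols]
        if model_name == "plsda":
            yhat = predict_plsda(model, Xp)
        else:
            yhat = predict_svm(model, Xp)
        m = metrics(confusion(sub.y_pred, yhat))
        rows.append({
            "config": i, "n_pred_ventral": n_v, "n_pred_reverse": n_r,
            "calibration_accuracy": cal_acc,
            "prediction_accuracy": _r(m.overall_accuracy),
            "viability_accuracy": _r(m.viability_accuracy),
            "final_germination": _r(m.final_germination),
            "f_measure": _r(m.f_measure),
        })
    return pd.DataFrame(rows)
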