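"""Spectral pre-processing: standard normal variate (SNV), multiplicative
scatter correction (MSC), and Savitzky-Golay derivative.

SNV and MSC remove multiplicative scatter and additive offsets; the SG
derivative (window 7, quadratic polynomial, first derivative, per
band-index step) suppresses baseline structure while preserving narrow
absorption features. The MSC reference is always the calibration-set mean
spectrum, frozen and reused for prediction rows so no information leaks
from the prediction set into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import SpectralDataset

METHODS = ("raw", "snv", "msc", "sg")


@dataclass(frozen=True)
class PreprocessSpec:
    method: str = "raw"
    sg_window: int = 7
    sg_polyorder: int = 2
    sg_deriv: int = 1
    msc_reference: str | np.ndarray = "calibration-mean"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must not exceed sg_polyorder")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with the sample (n-1) standard deviation."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 bands")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant spectrum: SNV undefined (zero variance)")
    return (x - x.mean()) / sd


def msc(spectrum: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Fit x ~ a + b*reference by OLS and return (x - a) / b."""
    x = np.asarray(spectrum, dtype=float)
    r = np.asarray(reference, dtype=float)
    if x.shape != r.shape:
        raise ValueError("spectrum and reference must have equal length")
    if r.std() == 0:
        raise ValueError("reference has zero variance")
    rc = r - r.mean()
    b = float(rc @ (x - x.mean())) / float(rc @ rc)
    if abs(b) < 1e-10:
        raise ValueError("spectrum uncorrelated with reference (|b| < 1e-10)")
    a = x.mean() - b * r.mean()
    return (x - a) / b


def sg_derivative(spectrum: np.ndarray, spec: PreprocessSpec | None = None) -> np.ndarray:
    """Savitzky-Golay derivative, expressed per band-index step; edge values
    come from the polynomial fits on the terminal windows."""
    spec = PreprocessSpec(method="sg") if spec is None else spec
    x = np.asarray(spectrum, dtype=float)
    if x.size < spec.sg_window:
        raise ValueError(
            f"spectrum has {x.size} bands, shorter than the SG window {spec.sg_window}"
        )
    return savgol_filter(
        x, spec.sg_window, spec.sg_polyorder, deriv=spec.sg_deriv, delta=1.0, mode="interp"
    )


def apply_preprocess(dataset: SpectralDataset, spec: PreprocessSpec) -> SpectralDataset:
    """Row-wise transform of a dataset; see module docstring for the MSC
    reference convention."""
    if dataset.X.shape[0] == 0:
        raise ValueError("empty dataset")
    if spec.method == "raw":
        return dataset.replace_X(dataset.X.copy())
    rows = []
    if spec.method == "msc":
        if isinstance(spec.msc_reference, str):
            if spec.msc_reference != "calibration-mean":
                raise ValueError("msc_reference must be a vector or 'calibration-mean'")
            if not dataset.is_cal.any():
                raise ValueError("MSC with 'calibration-mean' requires calibration rows")
            reference = dataset.X_cal.mean(axis=0)
        else:
            reference = np.asarray(spec.msc_reference, dtype=float)
    for i, x in enumerate(dataset.X):
        try:
            if spec.method == "snv":
                rows.append(snv(x))
            elif spec.method == "msc":
                rows.append(msc(x, reference))
            else:
                rows.append(sg_derivative(x, spec))
        except ValueError as exc:
            raise ValueError(f"pre-processing failed on row {i}: {exc}") from exc
    return dataset.replace_X(np.vstack(rows))
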