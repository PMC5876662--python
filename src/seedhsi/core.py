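"""Shared containers for the seed-viability pipeline.

Class labels follow the germination-assay convention: code 1 = germinated
(viable), code 2 = non-germinated (non-viable). Seeds are scanned on two
faces, the ventral groove side and the reverse (embryo-bearing) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VIABLE = 1
NONVIABLE = 2
SIDES = ("ventral", "reverse")
ROLES = ("calibration", "prediction")
DATASET_KINDS = ("ventral", "reverse", "mean", "mixture")

#: full sensor grid: 766 bands evenly spaced over 400-1000 nm, endpoints
#: inclusive (band spacing 600/765 nm).
FULL_GRID_NM = np.linspace(400.0, 1000.0, 766)


def check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    bad = set(np.unique(y)) - {VIABLE, NONVIABLE}
    if bad:
        raise ValueError(f"unknown class codes {sorted(bad)}; expected 1 (viable) or 2 (non-viable)")
    return y


@dataclass
class HyperspectralCube:
    """3-D reflectance/count array, rows x cols x bands, with wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray
    calibrated: bool = False
    side: str = "ventral"
    seed_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band dimension {self.data.shape[2]} does not match "
                f"wavelength count {self.wavelengths.size}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SeedMask:
    """Boolean ROI mask over a cube's spatial plane."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SeedSpectrum:
    """One seed-side's mean reflectance spectrum."""

    seed_id: str
    side: str
    label: int
    wavelengths: np.ndarray
    reflectance: np.ndarray
    role: str = "calibration"

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        self.label = int(self.label)
        if self.label not in (VIABLE, NONVIABLE):
            raise ValueError("label must be 1 (germinated) or 2 (non-germinated)")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != self.wavelengths.shape:
            raise ValueError("reflectance length must match wavelengths")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")


@dataclass
class SpectralDataset:
    """Labelled spectra matrix with calibration/prediction roles.

    ``meta`` carries per-row provenance: seed_id and side (or "mean").
    """

    kind: str
    X: np.ndarray
    y: np.ndarray
    roles: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.kind not in DATASET_KINDS:
            raise ValueError(f"kind must be one of {DATASET_KINDS}")
        self.X = np.asarray(self.X, dtype=float)
        self.y = check_labels(self.y)
        self.roles = np.asarray(self.roles)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n = self.X.shape[0]
        if not (self.y.size == n and self.roles.size == n):
            raise ValueError("X, y and roles must agree on the number of rows")
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError("column count must match wavelength count")

    @property
    def is_cal(self) -> np.ndarray:
        return self.roles == "calibration"

    @property
    def is_pred(self) -> np.ndarray:
        return self.roles == "prediction"

    @property
    def X_cal(self) -> np.ndarray:
        return self.X[self.is_cal]

    @property
    def y_cal(self) -> np.ndarray:
        return self.y[self.is_cal]

    @property
    def X_pred(self) -> np.ndarray:
        return self.X[self.is_pred]

    @property
    def y_pred(self) -> np.ndarray:
        return self.y[self.is_pred]

    def replace_X(self, X: np.ndarray, wavelengths: np.ndarray | None = None) -> "SpectralDataset":
        wl = self.wavelengths if wavelengths is None else wavelengths
        return SpectralDataset(
            kind=self.kind, X=np.asarray(X, dtype=float), y=self.y.copy(),
            roles=self.roles.copy(), wavelengths=np.asarray(wl, dtype=float),
            meta=self.meta.copy(),
        )


def spectra_to_frame(spectra: list[SeedSpectrum]) -> pd.DataFrame:
    """Tabulate spectra in the shared CSV dialect.

    Columns: ``seed_id, side, role, label, <wavelength nm to 2 decimals>...``
    """
    if not spectra:
        raise ValueError("no spectra to tabulate")
    wl = spectra[0].wavelengths
    for s in spectra:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("all spectra must share one wavelength grid")
    cols = [f"{w:.2f}" for w in wl]
    rows = pd.DataFrame([s.reflectance for s in spectra], columns=cols)
    head = pd.DataFrame(
        {
            "seed_id": [s.seed_id for s in spectra],
            "side": [s.side for s in spectra],
            "role": [s.role for s in spectra],
            "label": [s.label for s in spectra],
        }
    )
    return pd.concat([head, rows], axis=1)


def frame_to_spectra(frame: pd.DataFrame) -> list[SeedSpectrum]:
    """Inverse of :func:`spectra_to_frame`."""
    meta_cols = ["seed_id", "side", "role", "label"]
    wl_cols = [c for c in frame.columns if c not in meta_cols]
    wl = np.array([float(c) for c in wl_cols])
    out = []
    for _, row in frame.iterrows():
        out.append(
            SeedSpectrum(
                seed_id=str(row["seed_id"]), side=str(row["side"]),
                label=int(row["label"]), wavelengths=wl,
                reflectance=row[wl_cols].to_numpy(dtype=float),
                role=str(row["role"]),
            )
        )
    return out
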