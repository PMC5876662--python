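"""Synthetic seed-scan generator.

Emulates the spectral structure of two-side VIS/NIR scans of wheat seeds:
two classes (viable / non-viable) whose mean reflectance curves cross once —
near 691.5 nm on the ventral groove side and near 799.5 nm on the reverse
side, viable higher below the crossover — plus multiplicative scatter,
additive offset, smooth baseline drift and per-band white noise. Class
separation is additionally concentrated at configurable informative bands so
that wavelength-selection recovery can be tested against a known truth.

Raw hypercubes are produced by inverting the white/dark reflectance
calibration, so the acquisition pipeline can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import (
    FULL_GRID_NM,
    NONVIABLE,
    VIABLE,
    SeedSpectrum,
)

# Control points for the base (class-average) reflectance curve of a wheat
# seed: low in the blue, chlorophyll-related structure around 670 nm, red
# edge toward the NIR plateau, mild water-related dip near 970 nm. The two
# faces differ slightly in overall albedo.
_BASE_POINTS_NM = np.array([400.0, 450.0, 520.0, 600.0, 670.0, 720.0, 780.0, 860.0, 950.0, 1000.0])
_BASE_POINTS_R = {
    "ventral": np.array([0.14, 0.17, 0.24, 0.31, 0.34, 0.44, 0.52, 0.55, 0.52, 0.50]),
    "reverse": np.array([0.12, 0.15, 0.21, 0.28, 0.31, 0.41, 0.49, 0.52, 0.49, 0.47]),
}

DEFAULT_CROSSOVER_NM = {"ventral": 691.5, "reverse": 799.5}
DEFAULT_INFORMATIVE_BANDS_NM = (500.0, 680.0, 850.0)


@dataclass(frozen=True)
class ClassProfile:
    """Per-side mean reflectance curves of the two viability classes."""

    side: str
    wavelengths: np.ndarray
    viable_mean: np.ndarray
    nonviable_mean: np.ndarray
    crossover_nm: float

    def validate(self) -> None:
        diff = self.viable_mean - self.nonviable_mean
        below = self.wavelengths < self.crossover_nm
        if not (np.all(diff[below] > 0) and np.all(diff[~below] < 0)):
            raise ValueError("class means must cross exactly once, at crossover_nm")
        for m in (self.viable_mean, self.nonviable_mean):
            if not (np.all(m > 0.02) and np.all(m < 0.95)):
                raise ValueError("mean reflectance must stay within (0.02, 0.95)")

    def mean_for(self, label: int) -> np.ndarray:
        return self.viable_mean if label == VIABLE else self.nonviable_mean


@dataclass(frozen=True)
class NoiseSpec:
    """Within-class spectral noise: gain ~ lognormal(0, gain_sd) multiplies
    the class mean; offset ~ N(0, offset_sd) adds; a degree-2 Chebyshev
    baseline with coefficient scale ``baseline_amp`` drifts smoothly; white
    noise N(0, white_sd) is per band. Defaults are set so raw-spectra models
    are measurably hurt by scatter that SNV/MSC/derivatives can correct."""

    gain_sd: float = 0.08
    offset_sd: float = 0.01
    baseline_amp: float = 0.01
    white_sd: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gain_sd", "offset_sd", "baseline_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(gain_sd=0.0, offset_sd=0.0, baseline_amp=0.0, white_sd=0.0)


@dataclass(frozen=True)
class PopulationSpec:
    """Study design: sample sizes per role and class, per-side class
    profiles, noise model, and the wavelengths where class separation is
    concentrated. Defaults reproduce the study layout of 106 calibration
    seeds (75 viable + 31 non-viable) and 54 prediction seeds (38 + 16)."""

    n_cal_viable: int = 75
    n_cal_nonviable: int = 31
    n_pred_viable: int = 38
    n_pred_nonviable: int = 16
    separation: float = 0.05
    informative_bands_nm: tuple[float, ...] = DEFAULT_INFORMATIVE_BANDS_NM
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    profiles: dict[str, ClassProfile] | None = None

    def __post_init__(self) -> None:
        for name in ("n_cal_viable", "n_cal_nonviable", "n_pred_viable", "n_pred_nonviable"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.profiles is None:
            object.__setattr__(
                self,
                "profiles",
                {
                    side: make_class_profiles(
                        side,
                        separation=self.separation,
                        informative_bands_nm=self.informative_bands_nm,
                    )
                    for side in ("ventral", "reverse")
                },
            )

    @property
    def n_seeds(self) -> int:
        return (
            self.n_cal_viable + self.n_cal_nonviable
            + self.n_pred_viable + self.n_pred_nonviable
        )


def make_class_profiles(
    side: str,
    crossover_nm: float | None = None,
    separation: float = 0.05,
    informative_bands_nm: tuple[float, ...] = DEFAULT_INFORMATIVE_BANDS_NM,
    wavelengths: np.ndarray | None = None,
) -> ClassProfile:
    """Build smooth viable/non-viable mean curves for one seed face.

    The class difference is ``separation * tanh((crossover - nm)/15)``, so it
    is positive below the crossover and negative above with a single sign
    change, amplified by Gaussian bumps (sigma 5 nm) at the informative
    bands. The 15 nm transition width keeps the bump nearest the crossover
    locally dominant, so each informative band remains a recoverable
    feature. Default crossovers: 691.5 nm (ventral), 799.5 nm (reverse).
    """
    if side not in _BASE_POINTS_R:
        raise ValueError(f"side must be 'ventral' or 'reverse', got {side!r}")
    if crossover_nm is None:
        crossover_nm = DEFAULT_CROSSOVER_NM[side]
    if not (430.0 < crossover_nm < 970.0):
        raise ValueError(
            f"crossover_nm must lie inside (430, 970) nm, got {crossover_nm}"
        )
    if separation <= 0:
        raise ValueError("separation must be > 0 (classes must differ strictly)")
    nm = FULL_GRID_NM if wavelengths is None else np.asarray(wavelengths, dtype=float)

    base = PchipInterpolator(_BASE_POINTS_NM, _BASE_POINTS_R[side])(nm)

    shape = np.tanh((crossover_nm - nm) / 15.0)
    bumps = np.zeros_like(nm)
    for b in informative_bands_nm:
        bumps += np.exp(-0.5 * ((nm - b) / 5.0) ** 2)
    diff = separation * shape * (1.0 + 1.5 * bumps)

    profile = ClassProfile(
        side=side,
        wavelengths=nm,
        viable_mean=base + diff / 2.0,
        nonviable_mean=base - diff / 2.0,
        crossover_nm=float(crossover_nm),
    )
    profile.validate()
    return profile


def _baseline(n_bands: int, amp: float, rng: np.random.Generator) -> np.ndarray:
    # smooth degree-2 Chebyshev drift over the band axis
    u = np.linspace(-1.0, 1.0, n_bands)
    c = rng.normal(0.0, amp, size=3)
    return c[0] + c[1] * u + c[2] * (2.0 * u**2 - 1.0)


def simulate_seed_spectrum(
    profile: ClassProfile,
    label: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one seed-side spectrum: gain x class mean + offset + baseline +
    white noise, clipped into (0, 1]. With all noise scales at zero the
    class mean is returned exactly."""
    mean = profile.mean_for(label)
    gain = rng.lognormal(0.0, noise.gain_sd)
    offset = rng.normal(0.0, noise.offset_sd)
    base = _baseline(mean.size, noise.baseline_amp, rng)
    white = rng.normal(0.0, noise.white_sd, size=mean.size)
    return np.clip(gain * mean + offset + base + white, 1e-9, 1.0)


@dataclass
class RawScan:
    """One simulated acquisition: raw counts plus reference frames."""

    i0: np.ndarray
    white: np.ndarray
    black: np.ndarray
    wavelengths: np.ndarray
    mask: np.ndarray  # planted ground-truth seed pixels


def simulate_hypercube(
    spectrum: np.ndarray,
    geometry: tuple[int, int] = (48, 48),
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    wavelengths: np.ndarray | None = None,
    background_level: float = 0.05,
    seed_mask: np.ndarray | None = None,
) -> RawScan:
    """Invert the reflectance calibration to produce a raw line-scan cube.

    An elliptical seed region carries ``spectrum`` (with per-pixel white
    noise); the background carries a flat low reflectance, separable by
    thresholding at 830 nm. Counts are built as I0 = B + R*(W-B) + sensor
    noise, so ``calibrate(I0, W, B)`` recovers the planted reflectance up to
    that noise.
    """
    noise = NoiseSpec.silent() if noise is None else noise
    rng = np.random.default_rng(noise.rng_seed) if rng is None else rng
    spectrum = np.asarray(spectrum, dtype=float)
    nm = FULL_GRID_NM if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if spectrum.size != nm.size:
        raise ValueError("spectrum length must match the wavelength grid")
    rows, cols = geometry
    if rows < 8 or cols < 8:
        raise ValueError("degenerate geometry: both dimensions must be >= 8")

    i830 = int(np.argmin(np.abs(nm - 830.0)))
    if background_level >= 0.1:
        raise ValueError("background reflectance at 830 nm must be < 0.1")
    if spectrum[i830] <= 0.4:
        raise ValueError("seed reflectance at 830 nm must be > 0.4 for segmentation")

    if seed_mask is None:
        rr, cc = np.mgrid[0:rows, 0:cols]
        seed_mask = (
            ((rr - (rows - 1) / 2.0) / (rows * 0.30)) ** 2
            + ((cc - (cols - 1) / 2.0) / (cols * 0.22)) ** 2
        ) <= 1.0
    else:
        seed_mask = np.asarray(seed_mask, dtype=bool)
        if seed_mask.shape != (rows, cols):
            raise ValueError("seed_mask shape must match geometry")

    reflectance = np.full((rows, cols, nm.size), background_level)
    reflectance[seed_mask] = spectrum

    white = np.full((rows, cols, nm.size), 4000.0)
    black = np.full((rows, cols, nm.size), 100.0)
    counts = black + reflectance * (white - black)
    if noise.white_sd > 0:
        counts = counts + rng.normal(0.0, noise.white_sd * 3900.0, size=counts.shape)
    return RawScan(i0=counts, white=white, black=black, wavelengths=nm, mask=seed_mask)


@dataclass
class Population:
    """All simulated seeds of one study: two spectra per seed."""

    spectra: list[SeedSpectrum]
    spec: PopulationSpec
    wavelengths: np.ndarray

    @property
    def n_seeds(self) -> int:
        return len({s.seed_id for s in self.spectra})


def generate_population(spec: PopulationSpec | None = None, rng_seed: int | None = None) -> Population:
    """Simulate the full two-side study population.

    Seeds are laid out per the spec's counts (default 106 calibration + 54
    prediction = 160 seeds, 320 spectra); every seed gets a ventral and a
    reverse spectrum. Fully reproducible: one root seed spawns independent
    per-seed-side streams.
    """
    spec = PopulationSpec() if spec is None else spec
    root = spec.noise.rng_seed if rng_seed is None else rng_seed
    wl = spec.profiles["ventral"].wavelengths
    groups = [
        ("calibration", VIABLE, spec.n_cal_viable),
        ("calibration", NONVIABLE, spec.n_cal_nonviable),
        ("prediction", VIABLE, spec.n_pred_viable),
        ("prediction", NONVIABLE, spec.n_pred_nonviable),
    ]
    n_total = spec.n_seeds
    streams = np.random.SeedSequence(root).spawn(2 * n_total)
    spectra: list[SeedSpectrum] = []
    k = 0
    idx = 0
    for role, label, count in groups:
        for _ in range(count):
            idx += 1
            seed_id = f"seed_{idx:04d}"
            for side in ("ventral", "reverse"):
                rng = np.random.default_rng(streams[k])
                k += 1
                refl = simulate_seed_spectrum(spec.profiles[side], label, spec.noise, rng)
                spectra.append(
                    SeedSpectrum(
                        seed_id=seed_id, side=side, label=label,
                        wavelengths=wl, reflectance=refl, role=role,
                    )
                )
    return Population(spectra=spectra, spec=spec, wavelengths=wl.copy())


def with_seed(spec: PopulationSpec, rng_seed: int) -> PopulationSpec:
    """Return a copy of ``spec`` whose noise stream starts at ``rng_seed``."""
    return replace(spec, noise=replace(spec.noise, rng_seed=rng_seed))
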