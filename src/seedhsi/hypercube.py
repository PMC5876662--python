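"""Raw cube to per-seed mean spectrum: reflectance calibration, band
cropping, 830 nm threshold segmentation, and ROI averaging."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import HyperspectralCube, SeedMask, SeedSpectrum

#: spectra below/above these wavelengths are dominated by sensor noise and
#: are discarded; on the 766-band 400-1000 nm grid this keeps 688 bands.
CROP_LOW_NM = 430.0
CROP_HIGH_NM = 970.0

SEGMENT_BAND_NM = 830.0
MIN_ROI_PIXELS = 20

# 4-connectivity for seed blobs
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def calibrate(
    i0: np.ndarray | HyperspectralCube,
    white: np.ndarray,
    black: np.ndarray,
    wavelengths: np.ndarray | None = None,
    side: str = "ventral",
    seed_id: str = "",
) -> HyperspectralCube:
    """Reflectance calibration I = (I0 - B) / (W - B), clipped to [0, 1].

    ``white`` is a scan of a standard white tile (maximum reflectance),
    ``black`` a dark-current frame (no reflectance); both must match the raw
    cube's shape (or broadcast to it). Any element with W <= B is a
    singular reference and is rejected.
    """
    if isinstance(i0, HyperspectralCube):
        if wavelengths is None:
            wavelengths = i0.wavelengths
        side, seed_id = i0.side, i0.seed_id
        i0 = i0.data
    i0 = np.asarray(i0, dtype=float)
    if wavelengths is None:
        raise ValueError("wavelengths are required when calibrating a bare array")
    white = np.broadcast_to(np.asarray(white, dtype=float), i0.shape)
    black = np.broadcast_to(np.asarray(black, dtype=float), i0.shape)
    denom = white - black
    bad = denom <= 0
    if np.any(bad):
        n_bad = int(bad.sum())
        bands = np.unique(np.nonzero(bad)[-1])
        raise ZeroDivisionError(
            f"white reference does not exceed black in {n_bad} elements "
            f"(bands {bands[:10].tolist()}{'...' if bands.size > 10 else ''}); "
            "cannot divide by W - B"
        )
    refl = np.clip((i0 - black) / denom, 0.0, 1.0)
    return HyperspectralCube(
        data=refl, wavelengths=wavelengths, calibrated=True, side=side, seed_id=seed_id
    )


def crop_bands(
    obj: HyperspectralCube | SeedSpectrum,
    low_nm: float = CROP_LOW_NM,
    high_nm: float = CROP_HIGH_NM,
):
    """Keep exactly the bands whose wavelength lies in [low_nm, high_nm]."""
    if low_nm >= high_nm:
        raise ValueError("low_nm must be < high_nm")
    keep = (obj.wavelengths >= low_nm) & (obj.wavelengths <= high_nm)
    if not np.any(keep):
        raise ValueError(f"no bands inside [{low_nm}, {high_nm}] nm")
    if isinstance(obj, HyperspectralCube):
        return HyperspectralCube(
            data=obj.data[:, :, keep], wavelengths=obj.wavelengths[keep],
            calibrated=obj.calibrated, side=obj.side, seed_id=obj.seed_id,
        )
    return SeedSpectrum(
        seed_id=obj.seed_id, side=obj.side, label=obj.label,
        wavelengths=obj.wavelengths[keep], reflectance=obj.reflectance[keep],
        role=obj.role,
    )


def nearest_band(wavelengths: np.ndarray, nm: float) -> int:
    """Index of the band nearest ``nm``; ties resolve toward the lower
    wavelength."""
    return int(np.argmin(np.abs(np.asarray(wavelengths) - nm)))


def segment_seed(
    cube: HyperspectralCube,
    band_nm: float = SEGMENT_BAND_NM,
    threshold: float | str = "otsu",
    min_roi_pixels: int = MIN_ROI_PIXELS,
) -> SeedMask:
    """Threshold the (nearest-band) 830 nm reflectance image and keep the
    largest 4-connected component as the seed ROI."""
    if not cube.calibrated:
        raise ValueError("segmentation requires a calibrated cube")
    img = cube.data[:, :, nearest_band(cube.wavelengths, band_nm)]
    if threshold == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("no seed found: uniform image at the segmentation band")
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold)
    binary = img > thr
    labels, n = ndimage.label(binary, structure=_STRUCTURE)
    if n == 0:
        raise ValueError("no seed found: nothing above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = labels == best
    if mask.sum() < min_roi_pixels:
        raise ValueError(
            f"no seed found: largest component has {int(mask.sum())} pixels "
            f"(< {min_roi_pixels})"
        )
    return SeedMask(mask=mask)


def extract_mean_spectrum(
    cube: HyperspectralCube,
    mask: SeedMask,
    label: int = 1,
    seed_id: str | None = None,
) -> SeedSpectrum:
    """Per-band arithmetic mean of the reflectance over the ROI pixels."""
    m = mask.mask
    if m.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must match the cube's spatial dimensions")
    if not m.any():
        raise ValueError("empty mask")
    refl = cube.data[m].mean(axis=0)
    return SeedSpectrum(
        seed_id=cube.seed_id if seed_id is None else seed_id,
        side=cube.side, label=label,
        wavelengths=cube.wavelengths, reflectance=refl,
    )


def process_scan(
    i0, white, black, wavelengths, label: int = 1, side: str = "ventral",
    seed_id: str = "", low_nm: float = CROP_LOW_NM, high_nm: float = CROP_HIGH_NM,
    band_nm: float = SEGMENT_BAND_NM, threshold: float | str = "otsu",
) -> SeedSpectrum:
    """Full acquisition chain: calibrate, segment at 830 nm on the full-range
    cube, crop to [430, 970] nm, average the ROI."""
    cube = calibrate(i0, white, black, wavelengths, side=side, seed_id=seed_id)
    mask = segment_seed(cube, band_nm=band_nm, threshold=threshold)
    cube = crop_bands(cube, low_nm, high_nm)
    spec = extract_mean_spectrum(cube, mask, label=label, seed_id=seed_id)
    spec.role = "calibration"
    return spec
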