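"""Acquisition-chain tests: reflectance calibration, band cropping,
threshold segmentation, ROI averaging."""

import numpy as np
import pytest

from seedhsi.core import FULL_GRID_NM, HyperspectralCube, SeedMask
from seedhsi.envi import read_envi, write_envi
from seedhsi.hypercube import (
    calibrate,
    crop_bands,
    extract_mean_spectrum,
    nearest_band,
    process_scan,
    segment_seed,
)
from seedhsi.synthetic import make_class_profiles, simulate_hypercube


def _cube(data, wl=None, calibrated=True):
    data = np.asarray(data, dtype=float)
    if wl is None:
        wl = np.linspace(400, 1000, data.shape[2])
    return HyperspectralCube(data=data, wavelengths=wl, calibrated=calibrated)


class TestCalibrate:
    @pytest.mark.parametrize(
        "raw_of,expected",
        [
            (lambda w, b: b, 0.0),
            (lambda w, b: w, 1.0),
            (lambda w, b: (w + b) / 2, 0.5),
        ],
        ids=["dark-floor", "white-ceiling", "midpoint"],
    )
    def test_reference_conditions(self, raw_of, expected):
        w = np.full((4, 5, 6), 3000.0)
        b = np.full((4, 5, 6), 80.0)
        cube = calibrate(raw_of(w, b), w, b, np.linspace(400, 1000, 6))
        np.testing.assert_allclose(cube.data, expected)
        assert cube.calibrated

    def test_singular_reference_reports_offenders(self):
        w = np.full((3, 3, 4), 1000.0)
        b = np.full((3, 3, 4), 100.0)
        w[1, 1, 2] = 100.0
        with pytest.raises(ZeroDivisionError, match="1 elements"):
            calibrate(w * 0.5, w, b, np.linspace(400, 1000, 4))

    def test_output_clipped_to_unit_interval(self, rng):
        w = np.full((3, 3, 5), 1000.0)
        b = np.full((3, 3, 5), 100.0)
        raw = rng.uniform(0, 2000, size=(3, 3, 5))
        cube = calibrate(raw, w, b, np.linspace(400, 1000, 5))
        assert cube.data.min() >= 0.0 and cube.data.max() <= 1.0


class TestCropBands:
    def test_688_bands_on_the_full_sensor_grid(self):
        # independent enumeration oracle over the even 766-band grid
        expected = sum(1 for i in range(766) if 430.0 <= 400 + i * 600 / 765 <= 970.0)
        assert expected == 688
        cube = _cube(np.zeros((3, 3, 766)), FULL_GRID_NM)
        assert crop_bands(cube, 430, 970).wavelengths.size == expected

    def test_identity_crop_keeps_all_bands(self):
        cube = _cube(np.zeros((3, 3, 766)), FULL_GRID_NM)
        assert crop_bands(cube, 400, 1000).wavelengths.size == 766

    def test_empty_crop_rejected(self):
        cube = _cube(np.zeros((3, 3, 10)))
        with pytest.raises(ValueError, match="no bands"):
            crop_bands(cube, 2000, 3000)

    def test_idempotent(self, rng):
        cube = _cube(rng.uniform(size=(4, 4, 50)))
        once = crop_bands(cube, 500, 900)
        twice = crop_bands(once, 500, 900)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_commutes_with_calibrate(self, rng):
        wl = np.linspace(400, 1000, 40)
        raw = rng.uniform(200, 900, size=(5, 5, 40))
        w = np.full_like(raw, 1000.0)
        b = np.full_like(raw, 100.0)
        a = crop_bands(calibrate(raw, w, b, wl), 500, 900)
        bb = calibrate(
            crop_bands(_cube(raw, wl, calibrated=False), 500, 900).data,
            w[:, :, (wl >= 500) & (wl <= 900)],
            b[:, :, (wl >= 500) & (wl <= 900)],
            wl[(wl >= 500) & (wl <= 900)],
        )
        np.testing.assert_allclose(a.data, bb.data)


class TestSegmentSeed:
    def test_nearest_band_ties_resolve_to_lower_wavelength(self):
        wl = np.array([820.0, 840.0])
        assert nearest_band(wl, 830.0) == 0

    def test_planted_seed_recovered_with_numeric_threshold(self):
        data = np.full((20, 20, 5), 0.05)
        data[4:14, 5:17, :] = 0.6  # 120 pixels
        mask = segment_seed(_cube(data), threshold=0.3)
        assert mask.pixel_count == 120

    def test_uniform_background_has_no_seed(self):
        data = np.full((15, 15, 5), 0.05)
        with pytest.raises(ValueError, match="no seed found"):
            segment_seed(_cube(data), threshold=0.3)

    def test_largest_component_wins(self):
        data = np.full((30, 30, 4), 0.05)
        data[2:12, 2:12, :] = 0.7  # 100-pixel blob
        data[20:26, 20:25, :] = 0.7  # 30-pixel blob
        mask = segment_seed(_cube(data), threshold=0.3)
        # brute-force 4-connected flood fill oracle on the thresholded image
        img = data[:, :, 0] > 0.3
        seen = np.zeros_like(img, dtype=bool)
        sizes = []
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                if img[i, j] and not seen[i, j]:
                    stack, size = [(i, j)], 0
                    seen[i, j] = True
                    while stack:
                        a, b = stack.pop()
                        size += 1
                        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                            x, y = a + da, b + db
                            if 0 <= x < img.shape[0] and 0 <= y < img.shape[1] and img[x, y] and not seen[x, y]:
                                seen[x, y] = True
                                stack.append((x, y))
                    sizes.append(size)
        assert mask.pixel_count == max(sizes) == 100

    def test_otsu_threshold_separates_synthetic_contrast(self):
        p = make_class_profiles("ventral")
        scan = simulate_hypercube(p.viable_mean, geometry=(24, 24))
        cube = calibrate(scan.i0, scan.white, scan.black, scan.wavelengths)
        mask = segment_seed(cube, threshold="otsu")
        np.testing.assert_array_equal(mask.mask, scan.mask)

    def test_uncalibrated_cube_rejected(self):
        with pytest.raises(ValueError, match="calibrated"):
            segment_seed(_cube(np.zeros((10, 10, 3)), calibrated=False))


class TestExtractMeanSpectrum:
    def test_constant_roi_returns_shared_spectrum(self):
        s = np.linspace(0.2, 0.8, 6)
        data = np.tile(s, (8, 8, 1))
        mask = SeedMask(np.ones((8, 8), dtype=bool))
        out = extract_mean_spectrum(_cube(data), mask)
        np.testing.assert_allclose(out.reflectance, s)

    def test_two_pixel_average(self):
        data = np.zeros((1, 2, 4))
        data[0, 0, :] = 0.2
        data[0, 1, :] = 0.4
        out = extract_mean_spectrum(_cube(data), SeedMask(np.ones((1, 2), dtype=bool)))
        np.testing.assert_allclose(out.reflectance, 0.3)

    def test_matches_brute_force_loop(self, rng):
        data = rng.uniform(size=(10, 10, 7))
        mask = rng.uniform(size=(10, 10)) < 0.5
        mask.flat[:50] |= True  # ensure enough pixels
        expected = np.zeros(7)
        for band in range(7):
            vals = [data[i, j, band] for i in range(10) for j in range(10) if mask[i, j]]
            expected[band] = sum(vals) / len(vals)
        out = extract_mean_spectrum(_cube(data), SeedMask(mask))
        np.testing.assert_allclose(out.reflectance, expected, atol=1e-12)

    def test_permutation_invariant_and_linear(self, rng):
        data = rng.uniform(size=(6, 6, 5))
        mask = SeedMask(rng.uniform(size=(6, 6)) < 0.6)
        base = extract_mean_spectrum(_cube(data), mask).reflectance
        perm = rng.permutation(36)
        shuffled = data.reshape(36, 5)[perm].reshape(6, 6, 5)
        pmask = SeedMask(mask.mask.reshape(36)[perm].reshape(6, 6))
        np.testing.assert_allclose(
            np.sort(extract_mean_spectrum(_cube(shuffled), pmask).reflectance), np.sort(base)
        )
        np.testing.assert_allclose(
            extract_mean_spectrum(_cube(2.5 * data), mask).reflectance, 2.5 * base
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            extract_mean_spectrum(_cube(np.zeros((4, 4, 3))), SeedMask(np.zeros((4, 4), dtype=bool)))


class TestEndToEnd:
    def test_zero_noise_scan_reproduces_planted_spectrum(self):
        p = make_class_profiles("reverse")
        scan = simulate_hypercube(p.nonviable_mean, geometry=(24, 24))
        spec = process_scan(scan.i0, scan.white, scan.black, scan.wavelengths, label=2, side="reverse")
        keep = (FULL_GRID_NM >= 430) & (FULL_GRID_NM <= 970)
        assert spec.wavelengths.size == 688
        np.testing.assert_allclose(spec.reflectance, p.nonviable_mean[keep], atol=1e-10)

    def test_envi_roundtrip(self, rng, tmp_path):
        data = rng.uniform(size=(9, 7, 12)).astype(np.float32)
        wl = np.linspace(400, 1000, 12)
        write_envi(tmp_path / "cube", data, wl)
        cube = read_envi(tmp_path / "cube")
        np.testing.assert_allclose(cube.data, data, atol=1e-7)
        np.testing.assert_allclose(cube.wavelengths, wl, atol=1e-6)
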