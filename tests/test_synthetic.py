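"""Generator tests: class-profile geometry, noise model, hypercube
inversion, and population bookkeeping."""

import numpy as np
import pytest

from seedhsi.core import FULL_GRID_NM, NONVIABLE, VIABLE, spectra_to_frame
from seedhsi.hypercube import calibrate, segment_seed
from seedhsi.synthetic import (
    NoiseSpec,
    PopulationSpec,
    generate_population,
    make_class_profiles,
    simulate_hypercube,
    simulate_seed_spectrum,
)

from conftest import tiny_spec


class TestClassProfiles:
    @pytest.mark.parametrize(
        "side,crossover", [("ventral", 691.5), ("reverse", 799.5)]
    )
    def test_single_crossover_at_configured_wavelength(self, side, crossover):
        p = make_class_profiles(side, crossover, separation=0.05)
        diff = p.viable_mean - p.nonviable_mean
        below = p.wavelengths < crossover
        assert np.all(diff[below] > 0), "viable must be brighter below the crossover"
        assert np.all(diff[~below] < 0), "viable must be darker above the crossover"
        signs = np.sign(diff)
        assert np.count_nonzero(np.diff(signs)) == 1

    def test_ventral_sign_pattern_at_600_and_800nm(self):
        p = make_class_profiles("ventral", 691.5, separation=0.05)
        diff = p.viable_mean - p.nonviable_mean
        assert diff[np.argmin(np.abs(p.wavelengths - 600))] > 0
        assert diff[np.argmin(np.abs(p.wavelengths - 800))] < 0

    def test_reverse_flip_brackets_crossover(self):
        p = make_class_profiles("reverse", 799.5, separation=0.05)
        diff = p.viable_mean - p.nonviable_mean
        i = np.searchsorted(p.wavelengths, 799.5)
        assert diff[i - 1] > 0 > diff[i]

    def test_curves_smooth_and_in_range(self):
        for side in ("ventral", "reverse"):
            p = make_class_profiles(side)
            for m in (p.viable_mean, p.nonviable_mean):
                assert np.all((m > 0.02) & (m < 0.95))
                assert np.abs(np.diff(m)).max() < 0.05

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            make_class_profiles("ventral", 691.5, separation=0.0)

    @pytest.mark.parametrize("bad", [400.0, 430.0, 970.0, 1200.0])
    def test_crossover_outside_range_rejected_naming_interval(self, bad):
        with pytest.raises(ValueError, match=r"\(430, 970\)"):
            make_class_profiles("ventral", bad)


class TestSeedSpectrum:
    def test_zero_noise_returns_class_mean_exactly(self):
        p = make_class_profiles("ventral")
        rng = np.random.default_rng(0)
        for label in (VIABLE, NONVIABLE):
            s = simulate_seed_spectrum(p, label, NoiseSpec.silent(), rng)
            np.testing.assert_array_equal(s, p.mean_for(label))

    def test_same_seed_gives_identical_spectra(self):
        p = make_class_profiles("reverse")
        noise = NoiseSpec()
        a = simulate_seed_spectrum(p, VIABLE, noise, np.random.default_rng(7))
        b = simulate_seed_spectrum(p, VIABLE, noise, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_gain_noise_monte_carlo_mean(self):
        # with gain ~ lognormal(0, 0.1) only, the generative model's per-band
        # mean is exp(sigma^2/2) * class_mean; the 1000-draw sample mean must
        # sit within 3 standard errors of it
        p = make_class_profiles("ventral")
        noise = NoiseSpec(gain_sd=0.1, offset_sd=0.0, baseline_amp=0.0, white_sd=0.0)
        rng = np.random.default_rng(123)
        draws = np.array([simulate_seed_spectrum(p, VIABLE, noise, rng) for _ in range(1000)])
        sigma = 0.1
        model_mean = np.exp(sigma**2 / 2) * p.viable_mean
        se = p.viable_mean * np.sqrt((np.exp(sigma**2) - 1) * np.exp(sigma**2)) / np.sqrt(1000)
        assert np.all(np.abs(draws.mean(axis=0) - model_mean) < 3 * se + 1e-12)


class TestHypercube:
    def test_zero_noise_calibration_recovers_planted_reflectance(self):
        p = make_class_profiles("ventral")
        scan = simulate_hypercube(p.viable_mean, geometry=(16, 16))
        cube = calibrate(scan.i0, scan.white, scan.black, scan.wavelengths)
        np.testing.assert_allclose(
            cube.data[scan.mask], np.tile(p.viable_mean, (int(scan.mask.sum()), 1)), atol=1e-12
        )
        np.testing.assert_allclose(cube.data[~scan.mask], 0.05, atol=1e-12)

    def test_planted_mask_recovered_exactly(self):
        p = make_class_profiles("ventral")
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:14, 5:17] = True  # 120 pixels
        assert mask.sum() == 120
        scan = simulate_hypercube(p.viable_mean, geometry=(20, 20), seed_mask=mask)
        cube = calibrate(scan.i0, scan.white, scan.black, scan.wavelengths)
        found = segment_seed(cube, threshold=0.3)
        assert found.pixel_count == 120
        np.testing.assert_array_equal(found.mask, mask)

    def test_white_equal_black_breaks_calibration(self):
        p = make_class_profiles("ventral")
        scan = simulate_hypercube(p.viable_mean, geometry=(10, 10))
        white = scan.white.copy()
        white[0, 0, :] = scan.black[0, 0, :]
        with pytest.raises(ZeroDivisionError):
            calibrate(scan.i0, white, scan.black, scan.wavelengths)

    def test_degenerate_geometry_rejected(self):
        p = make_class_profiles("ventral")
        with pytest.raises(ValueError, match="geometry"):
            simulate_hypercube(p.viable_mean, geometry=(6, 40))


class TestPopulation:
    def test_default_counts_match_study_design(self, default_population):
        pop = default_population
        assert pop.n_seeds == 160
        assert len(pop.spectra) == 320
        roles = {}
        for s in pop.spectra:
            if s.side == "ventral":
                roles.setdefault(s.role, {VIABLE: 0, NONVIABLE: 0})[s.label] += 1
        assert roles["calibration"] == {VIABLE: 75, NONVIABLE: 31}
        assert roles["prediction"] == {VIABLE: 38, NONVIABLE: 16}

    def test_minimal_population(self):
        spec = tiny_spec(n_cal_viable=1, n_cal_nonviable=1, n_pred_viable=1, n_pred_nonviable=1)
        pop = generate_population(spec)
        assert pop.n_seeds == 4 and len(pop.spectra) == 8

    def test_single_seed_per_group(self):
        spec = PopulationSpec(n_cal_viable=1, n_cal_nonviable=1, n_pred_viable=0, n_pred_nonviable=0)
        pop = generate_population(spec)
        assert pop.n_seeds == 2 and len(pop.spectra) == 4

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            PopulationSpec(n_cal_viable=-1)

    def test_reruns_are_byte_identical(self):
        spec = tiny_spec(rng_seed=99)
        a = spectra_to_frame(generate_population(spec).spectra).to_csv(index=False)
        b = spectra_to_frame(generate_population(spec).spectra).to_csv(index=False)
        assert a == b

    def test_group_mean_difference_changes_sign_once_at_crossover(self):
        # 300 noisy spectra per class: the empirical mean difference must
        # cross zero exactly once, within 2 bands of the configured crossover
        p = make_class_profiles("ventral")
        noise = NoiseSpec()
        rng = np.random.default_rng(2024)
        v = np.mean([simulate_seed_spectrum(p, VIABLE, noise, rng) for _ in range(300)], axis=0)
        nv = np.mean([simulate_seed_spectrum(p, NONVIABLE, noise, rng) for _ in range(300)], axis=0)
        diff = v - nv
        flips = np.nonzero(np.diff(np.sign(diff)))[0]
        assert flips.size == 1
        crossing_nm = FULL_GRID_NM[flips[0]]
        band_step = FULL_GRID_NM[1] - FULL_GRID_NM[0]
        assert abs(crossing_nm - p.crossover_nm) <= 2 * band_step
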