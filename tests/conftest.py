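import numpy as np
import pytest

from seedhsi.synthetic import (
    NoiseSpec,
    PopulationSpec,
    generate_population,
    make_class_profiles,
)

TINY_GRID = np.linspace(400.0, 1000.0, 80)


def tiny_spec(rng_seed: int = 0, **kwargs) -> PopulationSpec:
    """Small population on an 80-band grid: fast enough for grid-runner and
    CLI tests while keeping both classes in every role."""
    profiles = {
        side: make_class_profiles(side, wavelengths=TINY_GRID) for side in ("ventral", "reverse")
    }
    defaults = dict(
        n_cal_viable=14, n_cal_nonviable=8, n_pred_viable=8, n_pred_nonviable=6,
        profiles=profiles, noise=NoiseSpec(rng_seed=rng_seed),
    )
    defaults.update(kwargs)
    return PopulationSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_population():
    return generate_population(tiny_spec())


@pytest.fixture(scope="session")
def default_population():
    """Study-sized population: 106 calibration + 54 prediction seeds."""
    return generate_population(PopulationSpec(), rng_seed=20260101)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
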