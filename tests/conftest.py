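import pytest

from tiltmet.environment import make_tilt_grid
from tiltmet.spectral import DEFAULT_GRID, load_cie1931
from tiltmet.synthetic import (
    EnvironmentGeneratorConfig,
    ReflectanceGeneratorConfig,
    generate_environment,
    generate_reflectances,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def cmf():
    return load_cie1931()


@pytest.fixture(scope="session")
def tilts():
    return make_tilt_grid("fibonacci")


@pytest.fixture(scope="session")
def outdoor_env():
    return generate_environment(
        EnvironmentGeneratorConfig(kind="two_zone_outdoor", seed=0, name="outdoor0")
    )


@pytest.fixture(scope="session")
def indoor_env():
    return generate_environment(
        EnvironmentGeneratorConfig(kind="low_contrast_indoor", seed=1, name="indoor0")
    )


@pytest.fixture(scope="session")
def uniform_env():
    return generate_environment(
        EnvironmentGeneratorConfig(kind="uniform", seed=0, name="uniform0")
    )


@pytest.fixture(scope="session")
def small_corpus():
    """40 synthetic reflectances with a 5% duplicate fraction."""
    cfg = ReflectanceGeneratorConfig(n_samples=40, seed=0)
    return generate_reflectances(cfg)


def random_xyz(rng, n, lo=1.0, hi=100.0):
    return rng.uniform(lo, hi, size=(n, 3))
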