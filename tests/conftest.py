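import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cdftkit import SyntheticSpec, apratoxin_fixture, generate_density_triplet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def apratoxins():
    """The seven packaged apratoxin energy records."""
    return apratoxin_fixture()


@pytest.fixture(scope="session")
def small_triplet():
    """A small synthetic density triplet (16^3 grid, fast)."""
    spec = SyntheticSpec(seed=42, grid_counts=(16, 16, 16), n_atoms=3,
                         electron_count=10)
    return generate_density_triplet(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
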