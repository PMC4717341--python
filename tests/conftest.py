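import numpy as np
import pytest
from hypothesis import settings

from infrapopgen import (
    build_species_datasets,
    paperlike_config,
    simulate_system,
)
from infrapopgen.io import metadata_from_frame

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20151124)


@pytest.fixture(scope="session")
def paperlike_system():
    """Default 17-species synthetic system (seeded)."""
    return simulate_system(paperlike_config(), seed=11)


@pytest.fixture(scope="session")
def paperlike_datasets(paperlike_system):
    sysm = paperlike_system
    loads = dict(zip(sysm.loads["species"], sysm.loads["median_load"]))
    return build_species_datasets(
        sysm.alignment, metadata_from_frame(sysm.metadata), loads
    )
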