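import numpy as np
import pytest

from itscan.synthetic_data import (
    SimulationConfig,
    compact_config,
    generate_bundle,
)


@pytest.fixture(scope="session")
def compact_bundle():
    """A small planted bundle: 5 LSU ITS sites in the kinetoplastid-like clade."""
    return generate_bundle(compact_config(11))


@pytest.fixture(scope="session")
def noits_bundle():
    """A specificity bundle with no planted ITSs."""
    return generate_bundle(compact_config(12, planted=False))


@pytest.fixture(scope="session")
def study_bundle():
    """The full default bundle mirroring the euglenozoan study design:
    12 euglenid + 5 metakinetoplastid LSU sites, 3 shared, one SSU
    expansion, two novel sites in one euglenid taxon."""
    return generate_bundle(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
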