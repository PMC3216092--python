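import numpy as np
import pytest

from tfa_cycle.core_io import TimeGrid
from tfa_cycle.synthetic_data import (
    SineProfile,
    SyntheticSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def grid36() -> TimeGrid:
    """36 points at 25-min spacing: three 300-min cycles, 12 samples each."""
    return TimeGrid(times=tuple(3973.0 + 25.0 * np.arange(36)))


@pytest.fixture(scope="session")
def ten_tf_profiles():
    return {f"TF{i}": SineProfile(phase_degrees=36.0 * i, amplitude=0.4)
            for i in range(10)}


@pytest.fixture(scope="session")
def noiseless_dataset(ten_tf_profiles):
    """200 genes x 10 sine TFs x 36 points, no noise, no missing cells."""
    spec = SyntheticSpec(profiles=dict(ten_tf_profiles), n_decoy_tfs=0,
                         noise_sd=0.0, missing_fraction=0.0, rng_seed=5)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def noisy_dataset(ten_tf_profiles):
    """Same design with log-scale noise sd 0.2."""
    spec = SyntheticSpec(profiles=dict(ten_tf_profiles), n_decoy_tfs=0,
                         noise_sd=0.2, missing_fraction=0.0, rng_seed=5)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def default_dataset():
    """The standard closed-loop fixture: 13 active TFs + 37 decoys."""
    return generate_dataset(SyntheticSpec(rng_seed=1))
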