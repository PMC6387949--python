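import numpy as np
import pytest

from emolink.synthetic import GroundTruthSpec, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but structurally complete cohort used across test modules."""
    spec = GroundTruthSpec(
        n_participants=6,
        n_lab_trials=4,
        n_sim_trials=16,
        rr_duration_s=90.0,
        seed=42,
    )
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
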