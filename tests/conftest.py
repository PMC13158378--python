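import numpy as np
import pytest

from falff.synthetic import CohortSpec, generate_atlas, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec():
    """A cohort small enough for fast unit tests."""
    return CohortSpec(
        n_per_group=3,
        n_frames=160,
        grid_shape=(10, 10, 10),
        atlas_rois=4,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_spec):
    return generate_atlas(tiny_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
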