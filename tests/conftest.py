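import numpy as np
import pytest

from sfcpipe import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20150114)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort spec shared by slower integration tests."""
    return CohortSpec(n_subjects=87, grid_dims=(12, 12, 12), n_timepoints=96, n_controls=30, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_maps(small_spec, small_cohort):
    from sfcpipe import compute_sfc_maps

    return compute_sfc_maps(small_cohort, small_spec.seed)
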