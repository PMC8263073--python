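import numpy as np
import pytest

from gaersnet import (
    CommunitySpec,
    correlation_matrix,
    default_atlas,
    default_study_spec,
    fisher_average,
    generate_atlas,
    generate_group_timeseries,
)


@pytest.fixture(scope="session")
def atlas72():
    return default_atlas()


@pytest.fixture(scope="session")
def study_spec():
    return default_study_spec()


@pytest.fixture(scope="session")
def mini_atlas():
    """12-region bilateral atlas (3 groups x 2 regions per hemisphere)."""
    return generate_atlas(6, {"sensorimotor": 2, "limbic": 2, "thalamus": 2})


@pytest.fixture(scope="session")
def group_average_matrix(atlas72, study_spec):
    """Fisher-averaged group matrix from 9 default-condition subjects."""
    subjects = generate_group_timeseries(
        atlas72, study_spec, n_subjects=9, n_timepoints=900, seed=42
    )
    return fisher_average([correlation_matrix(s) for s in subjects])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
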