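import numpy as np
import pytest

from truncpo import RightTruncatedSample, SimConfig, build_event_grid, generate


@pytest.fixture
def tiny_sample():
    """Three subjects, hand-checkable risk sets: y=(1,2,2), d=(1,1,1)."""
    return RightTruncatedSample(
        t=[1.0, 2.0, 3.0],
        r=[2.0, 3.0, 3.0],
        z=np.array([[0.0], [1.0], [0.0]]),
        covariate_names=("age",),
    )


@pytest.fixture
def two_point_sample():
    """Two subjects with a scalar 0/1 covariate; all quantities hand-computable."""
    return RightTruncatedSample(t=[1.0, 2.0], r=[2.0, 2.0], z=np.array([[0.0], [1.0]]))


@pytest.fixture
def five_sample():
    """Five subjects, two covariates, ties included; the brute-force fixture."""
    return RightTruncatedSample(
        t=[0.5, 1.0, 1.0, 1.7, 2.2],
        r=[1.1, 1.0, 2.5, 2.0, 2.4],
        z=np.array(
            [[0.2, 1.0], [1.4, 0.0], [0.7, 1.0], [1.9, 0.0], [0.3, 1.0]]
        ),
    )


@pytest.fixture(scope="session")
def sim_sample_300():
    """One right-truncated dataset of n=300 from the default design."""
    sample, rate = generate(SimConfig(n=300, seed=123))
    return sample


@pytest.fixture(scope="session")
def grid_300(sim_sample_300):
    return build_event_grid(sim_sample_300)
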