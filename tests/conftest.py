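import numpy as np
import pytest

from cubethin import TargetSpec, make_gaussian_chain


@pytest.fixture
def unit_normal():
    return TargetSpec(mean=[0.0], cov=[[1.0]])


@pytest.fixture
def gaussian_2d():
    return TargetSpec(mean=[0.5, -0.5], cov=[[2.0, 0.6], [0.6, 1.0]])


@pytest.fixture
def chain_2d(gaussian_2d):
    """Small seeded iid chain with scores, shared across tests."""
    return make_gaussian_chain(gaussian_2d, 500, seed=11, mode="iid")


def random_pd_target(d, rng):
    m = rng.standard_normal((d, d))
    cov = m @ m.T + 0.5 * np.eye(d)
    return TargetSpec(mean=rng.standard_normal(d), cov=cov)
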