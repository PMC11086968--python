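import numpy as np
import pytest

from parcurve import DesignPoints, KernelConfig, SimulationSetting, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_points(n=20, s=2, seed=0, balanced=True):
    """Random shared-position design with standard-normal responses."""
    r = np.random.default_rng(seed)
    x = r.uniform(0, 1, n)
    if balanced:
        groups = np.repeat([0, 1], s // 2)
    else:
        groups = np.array([0] * (s - 1) + [1])
    Y = r.normal(size=(n, len(groups)))
    return DesignPoints(positions=x, subject_groups=groups, responses=Y)


@pytest.fixture
def small_points():
    return make_points(n=20, s=2, seed=1)


@pytest.fixture
def small_config():
    return KernelConfig(m=2, lam=1e-4)


@pytest.fixture
def setting1():
    return SimulationSetting(setting_id=1, n=100, delta1=1.0, seed=7)


@pytest.fixture
def setting1_points(setting1):
    return generate(setting1)
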