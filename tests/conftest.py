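import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from axelrod_groups import CultureState, LatticeTopology, ModelConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lattice4():
    return LatticeTopology.build(4)


def random_state(rng, N=16, F=3, q=5) -> CultureState:
    return CultureState(rng.integers(0, q, size=(N, F)), q=q)


def make_config(**kw) -> ModelConfig:
    base = dict(L=4, F=3, q=5)
    base.update(kw)
    return ModelConfig(**base)
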