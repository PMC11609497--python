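import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from molkit import AccessKind, make_system
from molkit.fixtures import generate_system

settings.register_profile(
    "molkit", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("molkit")


@pytest.fixture
def small_pair():
    """One chain, 3 residues x 7 atoms: CA atoms land at indices 1, 8, 15."""
    return generate_system(n_chains=1, res_per_chain=3, atoms_per_res=7,
                           box_edge=5.0, seed=7)


@pytest.fixture
def system_factory():
    """Build a fresh System of any kind over a fresh copy of the fixture."""

    def build(kind=AccessKind.MutableSerial, **kw):
        params = dict(n_chains=1, res_per_chain=3, atoms_per_res=7,
                      box_edge=5.0, seed=7)
        params.update(kw)
        top, state = generate_system(**params)
        return make_system(top, state, kind)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
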