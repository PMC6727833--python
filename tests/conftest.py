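import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modnetsim import GeneratorConfig, generate_network
from modnetsim.network import ModularNetwork, canonical_edge

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mixed_net():
    """Default mixed-topology network (N=500, M_av=25, k=10, p=0.1/0.1)."""
    return generate_network(GeneratorConfig(seed=42))


def make_plain_network(n, edges, module_of=None, n_modules=1, abundance=None):
    """Bare single-guild network for targeted unit tests."""
    if module_of is None:
        module_of = np.zeros(n, dtype=np.int64)
    else:
        module_of = np.asarray(module_of, dtype=np.int64)
        n_modules = int(module_of.max()) + 1
    net = ModularNetwork(
        edges={canonical_edge(u, v) for u, v in edges},
        module_of=module_of,
        module_type={m: "random" for m in range(n_modules)},
        guild_of=np.zeros(n, dtype=np.int8),
        abundance=None if abundance is None else np.asarray(abundance, dtype=float),
    )
    net.validate()
    return net


@pytest.fixture
def star_net():
    """Star on 5 nodes: center 0 with 4 leaves."""
    return make_plain_network(5, [(0, i) for i in range(1, 5)])
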