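import numpy as np
import pytest

from refutesim import InitSpec, SimulationConfig, TopologyParams, TransitionParams
from refutesim.population import ContactStructure


def small_config(**overrides) -> SimulationConfig:
    """A fast, fully explicit configuration for unit tests."""
    defaults = dict(
        n=40,
        days=5,
        seed=7,
        transition=TransitionParams(f_s=0.01, f_r=0.02, lambda_gate=0.0),
        init=InitSpec(frac_s=0.1),
        topology=TopologyParams(mode="graph", graph_kind="erdos_renyi", p=0.3,
                                contacts_per_agent_per_day=2),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def config():
    return small_config()


def structure_from_pairs(n: int, pairs, contacts_per_day: int = 1) -> ContactStructure:
    """Build a ContactStructure directly from an explicit edge list."""
    from refutesim.population import _adjacency_from_pairs

    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    indptr, indices = _adjacency_from_pairs(n, pairs)
    return ContactStructure(
        mode="graph",
        indptr=indptr,
        indices=indices,
        contacts_per_agent_per_day=contacts_per_day,
    )
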