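import numpy as np
import pytest

from netinflux.network import Parameter, Reaction, ReactionNetwork, Species, StimulationCondition
from netinflux.synth import CascadeSpec, make_cascade_network


@pytest.fixture
def decay_network():
    """dy/dt = -k y, y(0) = 1, k = 1: everything is known in closed form."""
    return ReactionNetwork(
        "decay",
        [Species("y", 1.0, "P")],
        [Parameter("k", 1.0)],
        [Reaction("dec", {"y": -1}, "k*y")],
    )


@pytest.fixture
def decay_condition():
    return StimulationCondition("c1", {}, 1.0)


@pytest.fixture(scope="session")
def cascade2():
    """10-rate-constant two-tier cascade with annotation and conditions."""
    return make_cascade_network(CascadeSpec(n_tiers=2, seed=0))


@pytest.fixture(scope="session")
def cascade2_trajectories(cascade2):
    from netinflux.sensitivity import simulate_with_sensitivities

    net, _, conds = cascade2
    return [simulate_with_sensitivities(net, c) for c in conds]
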