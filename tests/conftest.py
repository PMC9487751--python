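import numpy as np
import pytest
from hypothesis import settings

import pregmeth as pm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-noise cohort with planted T2 effects (session-cached)."""
    cfg = pm.SimulationConfig(n_probes=1200, n_genes=120, seed=7)
    return pm.simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def null_cohort():
    """Two groups, no planted effects."""
    cfg = pm.SimulationConfig(
        n_probes=800,
        n_genes=80,
        seed=11,
        effects=(),
        groups=(("NP", 12, (0.6, 0.4)), ("T2", 12, (0.45, 0.55))),
    )
    return pm.simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def planted_network():
    cfg = pm.SimulationConfig(
        n_probes=800, n_genes=100, seed=3, network=pm.NetworkSpec(n_nodes=150, module_size=5)
    )
    ds, truth = pm.simulate_cohort(cfg)
    net, net_truth = pm.simulate_network(cfg, truth)
    return net, net_truth, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
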