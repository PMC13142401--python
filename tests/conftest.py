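import logging

import numpy as np
import pandas as pd
import pytest

from thermobgc import network as net
from thermobgc.sim import SimConfig, simulate_study

logging.getLogger("thermobgc").setLevel(logging.ERROR)


def edges_frame(rows):
    return pd.DataFrame(rows, columns=["bgc_a", "bgc_b", "distance"])


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across read-only tests."""
    cfg = SimConfig(seed=42)
    env, inventory, networks, taxonomy, truth = simulate_study(cfg)
    return cfg, env, inventory, networks, taxonomy, truth


@pytest.fixture(scope="session")
def default_families(default_study):
    """Per-class GCFs derived from the default study networks."""
    _, env, inventory, networks, _, _ = default_study
    fams = []
    for cls, edges in networks.items():
        nodes = set(inventory.loc[inventory["bgc_class"] == cls, "bgc_id"])
        nodes |= set(edges["bgc_a"]) | set(edges["bgc_b"])
        nw = net.build_network(edges, nodes=nodes, bgc_class=cls)
        fams.extend(net.connected_components(nw))
    return fams


@pytest.fixture
def rng():
    return np.random.default_rng(0)
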