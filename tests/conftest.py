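"""Shared fixtures: small generated families and 2000-node grown networks.

Expensive objects are session-scoped and reused across test modules; every
fixture is built from a fixed seed so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppifam import (
    FOUniverse,
    GrowthParams,
    NetworkFamily,
    PPINetwork,
    ScoreStore,
    SynthesisConfig,
    build_cg_seed,
    build_duplication_seed,
    grow,
    synthesize_family,
)
from ppifam.graph_core import EVENT_SEED
from ppifam.io_cli import read_newick


def grown_network(model: str, size: int, seed: int) -> PPINetwork:
    rng = np.random.default_rng(seed)
    params = GrowthParams(model=model)
    if model == "CG":
        net = build_cg_seed(rng)
    else:
        net = build_duplication_seed(params, rng)
    fo = FOUniverse(next_fresh=net.n_nodes + 2)
    grow(net, size - net.n_nodes, params, rng, fo=fo)
    return net


@pytest.fixture(scope="session")
def dmc_net_2000() -> PPINetwork:
    return grown_network("DMC", 2000, seed=4)


@pytest.fixture(scope="session")
def cg_net_2000() -> PPINetwork:
    return grown_network("CG", 2000, seed=0)


@pytest.fixture(scope="session")
def small_family() -> NetworkFamily:
    """Tiny two-leaf family used for IO, evaluation and invariant checks."""
    tree = read_newick("(A:40,B:40)R;")
    config = SynthesisConfig(
        ancestral_size=120, growth=GrowthParams(model="DMC"), rng_seed=7
    )
    return synthesize_family(tree, config)


@pytest.fixture(scope="session")
def pairwise_family() -> NetworkFamily:
    """The canonical two-leaf benchmark shape: ancestor 2000, leaves 3000/4000."""
    tree = read_newick("(A:1000,B:2000)R;")
    config = SynthesisConfig(
        ancestral_size=2000, growth=GrowthParams(model="DMC"), rng_seed=1
    )
    return synthesize_family(tree, config)


def make_toy_family(annotations: dict[str, str]) -> NetworkFamily:
    """Family stub from explicit node -> FO label assignments (no edges).

    Node IDs follow the usual ``<network>.<integer>`` scheme; networks are
    inferred from the ID prefixes.
    """
    networks: dict[str, PPINetwork] = {}
    fo = FOUniverse()
    for node, label in annotations.items():
        net_id = node.rpartition(".")[0]
        net = networks.setdefault(net_id, PPINetwork(network_id=net_id))
        net.graph.add_node(node)
        net.annotation[node] = label
        net.lineage[node] = (None, EVENT_SEED)
        fo.register(label)
    return NetworkFamily(networks=networks, scores=ScoreStore(), fo=fo)
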