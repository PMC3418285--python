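"""Seed networks and single-step growth operators (DMC, DMR, CG).

Three growth mechanisms are provided:

* **DMC** (duplication-mutation-complementation): duplicate a random node's
  neighborhood; for each duplicated edge pair keep exactly one at risk and
  delete it with probability ``q_del``; finally link duplicate and original
  with probability ``q_con``.
* **DMR** (duplication with random mutation): duplicate a random node's
  neighborhood; delete each copied edge independently with probability
  ``q_del``; attach the duplicate to each non-neighbor of the original
  independently with probability ``q_new / N``.
* **CG** (crystal growth): module-oriented growth.  A new node either founds
  a module of its own (probability ``p_new``) and wires ``m`` edges by the
  anti-preferential rule, or joins a uniformly chosen module through an
  anchor selected anti-preferentially inside it, connecting to ``m`` of the
  anchor's neighbors.  Modules come from greedy (Newman fast-greedy)
  modularity maximization and are refreshed on a cadence proportional to
  network size.

All randomness flows through a single ``numpy.random.Generator``; node
iteration order is always sorted, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from ppifam.graph_core import (
    EVENT_ANCESTRAL,
    EVENT_DIV_DUP,
    EVENT_DIV_NEW_MODULE,
    EVENT_SEED,
    UNANNOTATED,
    FOUniverse,
    PPINetwork,
    node_sort_key,
)

DMC = "DMC"
DMR = "DMR"
CG = "CG"
MODELS = (DMC, DMR, CG)

#: number of anchor re-draws in a CG step before the fallback wiring kicks in
_CG_ANCHOR_RETRIES = 10


@dataclass
class GrowthParams:
    """Parameters of the growth models.

    The probability defaults sit in the ranges the duplication-divergence and
    crystal-growth literature reports for fits to the yeast interactome; they
    are advisory and fully exposed in configuration.
    """

    model: str = DMC
    dmc_q_del: float = 0.7
    dmc_q_con: float = 0.1
    dmr_q_del: float = 0.59
    dmr_q_new: float = 0.24
    cg_p_new: float = 0.1
    cg_m: int = 2
    cg_refresh_fraction: float = 0.1
    seed_bridge_edges: int = 5

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown growth model {self.model!r}; choose from {MODELS}")
        for name in ("dmc_q_del", "dmc_q_con", "dmr_q_del", "cg_p_new"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.dmr_q_new < 0:
            raise ValueError("dmr_q_new must be non-negative")
        if self.cg_m < 1:
            raise ValueError("cg_m must be >= 1")
        if self.cg_refresh_fraction <= 0:
            raise ValueError("cg_refresh_fraction must be > 0")
        if self.seed_bridge_edges < 0:
            raise ValueError("seed_bridge_edges must be >= 0")


# -- seed networks -------------------------------------------------------------


def build_duplication_seed(
    params: GrowthParams,
    rng: np.random.Generator,
    fo: Optional[FOUniverse] = None,
    network_id: str = "R",
) -> PPINetwork:
    """Seed for the duplication-based models (DMC, DMR): 50 nodes.

    Two cliques — one of 10 nodes (FO group F1) and one of 7 nodes (F2) —
    joined by ``seed_bridge_edges`` random inter-clique edges; each of the
    remaining 33 peripheral nodes hangs off one uniformly chosen clique node
    and founds a singleton FO group of its own.
    """
    if fo is None:
        fo = FOUniverse()
    net = PPINetwork(network_id=network_id)
    f1, f2 = fo.fresh(), fo.fresh()
    clique_a = [net.new_node(f1, None, EVENT_SEED) for _ in range(10)]
    clique_b = [net.new_node(f2, None, EVENT_SEED) for _ in range(7)]
    for group in (clique_a, clique_b):
        for i, u in enumerate(group):
            for v in group[i + 1 :]:
                net.add_edge(u, v)
    # random inter-clique bridges, distinct pairs
    bridges: set[tuple[str, str]] = set()
    while len(bridges) < params.seed_bridge_edges:
        u = clique_a[rng.integers(len(clique_a))]
        v = clique_b[rng.integers(len(clique_b))]
        bridges.add((u, v))
    for u, v in sorted(bridges):
        net.add_edge(u, v)
    clique_nodes = clique_a + clique_b
    for _ in range(33):
        node = net.new_node(fo.fresh(), None, EVENT_SEED)
        anchor = clique_nodes[rng.integers(len(clique_nodes))]
        net.add_edge(node, anchor)
    return net


def build_cg_seed(
    rng: np.random.Generator,
    fo: Optional[FOUniverse] = None,
    network_id: str = "R",
    topology: str = "cycle",
) -> PPINetwork:
    """Seed for the crystal-growth model: 4 connected nodes, one FO group each.

    Default topology is a 4-cycle; ``"path"`` and ``"complete"`` are also
    accepted for experimentation.
    """
    if fo is None:
        fo = FOUniverse()
    net = PPINetwork(network_id=network_id)
    nodes = [net.new_node(fo.fresh(), None, EVENT_SEED) for _ in range(4)]
    if topology == "cycle":
        edges = [(0, 1), (1, 2), (2, 3), (3, 0)]
    elif topology == "path":
        edges = [(0, 1), (1, 2), (2, 3)]
    elif topology == "complete":
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    else:
        raise ValueError(f"unknown CG seed topology {topology!r}")
    for i, j in edges:
        net.add_edge(nodes[i], nodes[j])
    return net


# -- step operators ------------------------------------------------------------


def _choose_uniform(items: list[str], rng: np.random.Generator) -> str:
    return items[rng.integers(len(items))]


def dmc_step(
    net: PPINetwork,
    params: GrowthParams,
    rng: np.random.Generator,
    event: str = EVENT_ANCESTRAL,
    fo_label: str = UNANNOTATED,
) -> tuple[str, str]:
    """One DMC growth step, in place; returns ``(new_node_id, source_node_id)``."""
    if net.n_nodes == 0:
        raise ValueError("cannot grow an empty network")
    u = _choose_uniform(net.nodes_sorted(), rng)
    neighbors = net.neighbors_sorted(u)
    v = net.new_node(fo_label, u, event)
    for w in neighbors:
        net.add_edge(v, w)
    for w in neighbors:
        # two-stage rule: pick which of the duplicated pair is at risk, then
        # delete it with probability q_del
        at_risk = (u, w) if rng.integers(2) == 0 else (v, w)
        if rng.random() < params.dmc_q_del:
            net.graph.remove_edge(*at_risk)
    if rng.random() < params.dmc_q_con:
        net.add_edge(u, v)
    return v, u


def dmr_step(
    net: PPINetwork,
    params: GrowthParams,
    rng: np.random.Generator,
    event: str = EVENT_ANCESTRAL,
    fo_label: str = UNANNOTATED,
) -> tuple[str, str]:
    """One DMR growth step, in place; returns ``(new_node_id, source_node_id)``."""
    if net.n_nodes == 0:
        raise ValueError("cannot grow an empty network")
    n_before = net.n_nodes
    u = _choose_uniform(net.nodes_sorted(), rng)
    neighbors = net.neighbors_sorted(u)
    v = net.new_node(fo_label, u, event)
    for w in neighbors:
        net.add_edge(v, w)
    for w in neighbors:
        if rng.random() < params.dmr_q_del:
            net.graph.remove_edge(v, w)
    # random attachment to nodes not adjacent to the original, excluding u and v
    neighbor_set = set(neighbors)
    candidates = [
        x for x in net.nodes_sorted() if x not in neighbor_set and x not in (u, v)
    ]
    if candidates:
        p_attach = min(1.0, params.dmr_q_new / n_before)
        hits = rng.random(len(candidates)) < p_attach
        for x, hit in zip(candidates, hits):
            if hit:
                net.add_edge(v, x)
    return v, u


def anti_preferential_choice(
    candidates: list[str] | set[str],
    net: PPINetwork,
    rng: np.random.Generator,
) -> str:
    """Sample a candidate with probability proportional to ``1 / (degree + 1)``."""
    pool = sorted(candidates, key=node_sort_key)
    if not pool:
        raise ValueError("anti-preferential choice from an empty candidate set")
    weights = np.array([1.0 / (net.degree(n) + 1) for n in pool])
    weights /= weights.sum()
    return pool[rng.choice(len(pool), p=weights)]


def detect_modules(net: PPINetwork) -> list[set[str]]:
    """Partition the network into modules by greedy modularity maximization.

    Uses the fast-greedy agglomeration (Clauset-Newman-Moore); edge-free
    graphs fall back to singleton modules.  The result is deterministically
    ordered by each module's smallest node ID.
    """
    if net.n_nodes == 0:
        return []
    if net.n_edges == 0:
        return [{n} for n in net.nodes_sorted()]
    # rebuild with sorted insertion order so tie-breaking is reproducible
    g = nx.Graph()
    g.add_nodes_from(net.nodes_sorted())
    g.add_edges_from(sorted((tuple(sorted(e, key=node_sort_key)) for e in net.graph.edges)))
    communities = nx.community.greedy_modularity_communities(g)
    modules = [set(c) for c in communities]
    return sorted(modules, key=lambda m: node_sort_key(min(m, key=node_sort_key)))


def _ap_sample_without_replacement(
    candidates: list[str], k: int, net: PPINetwork, rng: np.random.Generator
) -> list[str]:
    pool = sorted(candidates, key=node_sort_key)
    chosen: list[str] = []
    for _ in range(min(k, len(pool))):
        pick = anti_preferential_choice(pool, net, rng)
        chosen.append(pick)
        pool.remove(pick)
    return chosen


def cg_step(
    net: PPINetwork,
    modules: list[set[str]],
    params: GrowthParams,
    rng: np.random.Generator,
    event_anchored: str = EVENT_ANCESTRAL,
    event_new_module: str = EVENT_ANCESTRAL,
    fo_label: str = UNANNOTATED,
) -> tuple[str, Optional[str], list[set[str]]]:
    """One CG growth step, in place.

    Returns ``(new_node_id, anchor_node_or_None, updated_modules)``.  The
    module partition is updated incrementally (the new node joins its
    module); full recomputation happens on the caller's cadence.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot grow an empty network")
    if rng.random() < params.cg_p_new:
        # found a new module; wire m anti-preferential edges network-wide
        targets = _ap_sample_without_replacement(
            net.nodes_sorted(), params.cg_m, net, rng
        )
        v = net.new_node(fo_label, None, event_new_module)
        for w in targets:
            net.add_edge(v, w)
        return v, None, modules + [{v}]
    # join an existing module via an anchor with enough neighbors
    anchor: Optional[str] = None
    module_idx = -1
    for _ in range(_CG_ANCHOR_RETRIES):
        module_idx = int(rng.integers(len(modules)))
        candidate = anti_preferential_choice(modules[module_idx], net, rng)
        if net.degree(candidate) >= params.cg_m:
            anchor = candidate
            break
    if anchor is None:
        # fallback: last drawn anchor, connect to it and all its neighbors
        anchor = anti_preferential_choice(modules[module_idx], net, rng)
        neighbors = net.neighbors_sorted(anchor)
        v = net.new_node(fo_label, anchor, event_anchored)
        net.add_edge(v, anchor)
        for w in neighbors:
            net.add_edge(v, w)
    else:
        # connect to the anchor plus cg_m - 1 of its neighbors: each selected
        # neighbor closes a triangle with the anchor, which is what gives
        # crystal growth its dense, module-centred clustering
        neighbors = net.neighbors_sorted(anchor)
        v = net.new_node(fo_label, anchor, event_anchored)
        net.add_edge(v, anchor)
        if params.cg_m > 1:
            picks = rng.choice(len(neighbors), size=params.cg_m - 1, replace=False)
            for i in picks:
                net.add_edge(v, neighbors[int(i)])
    new_modules = [set(m) for m in modules]
    new_modules[module_idx].add(v)
    return v, anchor, new_modules


# -- multi-step growth ---------------------------------------------------------


def grow(
    net: PPINetwork,
    n_new: int,
    params: GrowthParams,
    rng: np.random.Generator,
    annotation_policy: str = "ancestral",
    fo: Optional[FOUniverse] = None,
) -> list[tuple[str, Optional[str], str]]:
    """Apply ``n_new`` growth steps of the configured model, in place.

    ``annotation_policy`` is either ``"ancestral"`` (each new node founds a
    fresh FO group — requires ``fo``) or ``"deferred"`` (new nodes are left
    unannotated for the family-synthesis layer to resolve by inheritance).

    Returns the growth log: ``(new_node, source_or_anchor_or_None, event)``
    in order of addition.
    """
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if annotation_policy not in ("ancestral", "deferred"):
        raise ValueError(f"unknown annotation policy {annotation_policy!r}")
    if annotation_policy == "ancestral" and fo is None:
        raise ValueError("the 'ancestral' policy needs an FOUniverse to issue labels")

    ancestral = annotation_policy == "ancestral"
    if ancestral:
        ev_dup = ev_new_mod = EVENT_ANCESTRAL
    else:
        ev_dup, ev_new_mod = EVENT_DIV_DUP, EVENT_DIV_NEW_MODULE

    log: list[tuple[str, Optional[str], str]] = []
    modules: list[set[str]] = []
    steps_until_refresh = 0
    for _ in range(n_new):
        label = fo.fresh() if ancestral else UNANNOTATED
        if params.model == DMC:
            v, src = dmc_step(net, params, rng, event=ev_dup, fo_label=label)
            log.append((v, src, ev_dup))
        elif params.model == DMR:
            v, src = dmr_step(net, params, rng, event=ev_dup, fo_label=label)
            log.append((v, src, ev_dup))
        else:
            if steps_until_refresh <= 0:
                modules = detect_modules(net)
                steps_until_refresh = max(
                    1, round(params.cg_refresh_fraction * net.n_nodes)
                )
            v, anchor, modules = cg_step(
                net,
                modules,
                params,
                rng,
                event_anchored=ev_dup,
                event_new_module=ev_new_mod,
                fo_label=label,
            )
            steps_until_refresh -= 1
            log.append((v, anchor, ev_dup if anchor is not None else ev_new_mod))
    return log
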