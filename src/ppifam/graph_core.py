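"""Core data model: networks, annotations, phylogenies, scores, families.

Node identifiers follow the scheme ``"<network_id>.<integer>"``.  The integer
suffix is preserved when a network is duplicated at a bifurcation, so the
counterpart of node ``"A.7"`` in a sibling network ``B`` is simply ``"B.7"``
— no extra correspondence table is needed to recover the ground truth.

The unannotated state is an explicit sentinel (``"-"``), never a missing map
entry: a node absent from the annotation map is an invariant violation, not
an unannotated protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import networkx as nx

#: Annotation sentinel for proteins of unknown function.
UNANNOTATED = "-"

# Lineage event tags.
EVENT_SEED = "seed"
EVENT_ANCESTRAL = "ancestral-growth"
EVENT_DUP_COPY = "duplication-copy"
EVENT_DIV_DUP = "divergence-duplicate"
EVENT_DIV_NEW_MODULE = "divergence-new-module"

VALID_EVENTS = frozenset(
    {EVENT_SEED, EVENT_ANCESTRAL, EVENT_DUP_COPY, EVENT_DIV_DUP, EVENT_DIV_NEW_MODULE}
)


def network_of(node_id: str) -> str:
    """Network label of a node ID (everything before the last ``"."``)."""
    prefix, _, _ = node_id.rpartition(".")
    return prefix


def node_sort_key(node_id: str) -> tuple[str, int]:
    """Sort key ordering nodes by network label, then integer suffix."""
    prefix, _, suffix = node_id.rpartition(".")
    return (prefix, int(suffix))


class FOUniverse:
    """Registry of functional-orthology (FO) group labels.

    Labels are ``"F1", "F2", ...`` and are never reused; the unannotated
    sentinel is not a member.
    """

    def __init__(self, next_fresh: int = 1) -> None:
        self.labels: list[str] = []
        self._seen: set[str] = set()
        self.next_fresh = next_fresh

    def fresh(self) -> str:
        """Issue a new, never-before-used FO label."""
        label = f"F{self.next_fresh}"
        self.next_fresh += 1
        self.labels.append(label)
        self._seen.add(label)
        return label

    def register(self, label: str) -> None:
        """Record an externally observed label (used when loading from disk)."""
        if label == UNANNOTATED:
            return
        if label not in self._seen:
            self._seen.add(label)
            self.labels.append(label)
            if label.startswith("F"):
                try:
                    idx = int(label[1:])
                except ValueError:
                    return
                self.next_fresh = max(self.next_fresh, idx + 1)

    def __contains__(self, label: str) -> bool:
        return label in self._seen

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class PPINetwork:
    """Undirected simple graph with FO annotations and per-node lineage.

    Parameters
    ----------
    network_id
        Short label, e.g. ``"A"``.  Must not contain ``"."``.
    graph
        ``networkx.Graph`` holding topology.  Nodes are full node IDs.
    annotation
        Node ID -> FO label, or :data:`UNANNOTATED`.
    lineage
        Node ID -> ``(source node ID or None, event tag)``.
    next_index
        Next integer suffix to issue for a new node.
    """

    network_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    annotation: dict[str, str] = field(default_factory=dict)
    lineage: dict[str, tuple[Optional[str], str]] = field(default_factory=dict)
    next_index: int = 1

    def __post_init__(self) -> None:
        if "." in self.network_id or not self.network_id:
            raise ValueError(
                f"network_id must be a non-empty string without '.': {self.network_id!r}"
            )

    # -- construction helpers -------------------------------------------------

    def new_node(self, fo_label: str, source: Optional[str], event: str) -> str:
        """Add a fresh node with the next free integer suffix; return its ID."""
        node = f"{self.network_id}.{self.next_index}"
        self.next_index += 1
        self.graph.add_node(node)
        self.annotation[node] = fo_label
        self.lineage[node] = (source, event)
        return node

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u}")
        self.graph.add_edge(u, v)

    # -- queries --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_sorted(self) -> list[str]:
        return sorted(self.graph.nodes, key=node_sort_key)

    def neighbors_sorted(self, node: str) -> list[str]:
        return sorted(self.graph.neighbors(node), key=node_sort_key)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def fo_index(self) -> dict[str, list[str]]:
        """FO label -> sorted list of member nodes (sentinel excluded)."""
        index: dict[str, list[str]] = {}
        for node in self.nodes_sorted():
            label = self.annotation[node]
            if label != UNANNOTATED:
                index.setdefault(label, []).append(node)
        return index


def copy_network(net: PPINetwork, new_id: str) -> PPINetwork:
    """Duplicate a network under a new label.

    Topology and annotations are preserved; node IDs are re-prefixed with
    ``new_id`` keeping their integer suffixes, and every node's lineage points
    back at its counterpart in ``net`` with the duplication-copy event tag.
    """
    mapping = {
        node: f"{new_id}.{node.rpartition('.')[2]}" for node in net.graph.nodes
    }
    copy = PPINetwork(network_id=new_id)
    copy.graph.add_nodes_from(mapping.values())
    copy.graph.add_edges_from((mapping[u], mapping[v]) for u, v in net.graph.edges)
    copy.annotation = {mapping[n]: net.annotation[n] for n in net.graph.nodes}
    copy.lineage = {mapping[n]: (n, EVENT_DUP_COPY) for n in net.graph.nodes}
    copy.next_index = net.next_index
    return copy


def validate(net: PPINetwork) -> list[str]:
    """Check the PPINetwork invariants; return a list of violations (empty = pass)."""
    violations: list[str] = []
    nodes = set(net.graph.nodes)
    for u, v in net.graph.edges:
        if u == v:
            violations.append(f"self-loop on {u}")
    for node in nodes:
        if network_of(node) != net.network_id:
            violations.append(
                f"node {node} not prefixed with network_id {net.network_id!r}"
            )
        if node not in net.annotation:
            violations.append(f"node {node} missing from annotation map")
        if node not in net.lineage:
            violations.append(f"node {node} missing from lineage map")
    for node in net.annotation:
        if node not in nodes:
            violations.append(f"annotation entry for unknown node {node}")
    for node, (source, event) in net.lineage.items():
        if node not in nodes:
            violations.append(f"lineage entry for unknown node {node}")
        if event not in VALID_EVENTS:
            violations.append(f"node {node} has unknown lineage event {event!r}")
    return violations


# -- phylogeny ----------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a rooted binary phylogeny.

    ``branch_length`` is the integer number of network nodes added while
    diverging this node's network from its parent's; it is 0 for the root.
    """

    name: str
    branch_length: int = 0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Rooted binary tree guiding family synthesis."""

    root: TreeNode

    def validate(self) -> None:
        """Raise ``ValueError`` on non-binary nodes, bad lengths, or name clashes."""
        names: set[str] = set()
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise ValueError(
                    f"tree node {node.name!r} has {len(node.children)} children; "
                    "the phylogeny must be strictly binary"
                )
            if node.branch_length < 0 or node.branch_length != int(node.branch_length):
                raise ValueError(
                    f"branch length of {node.name!r} must be a non-negative integer"
                )
            if node.name in names:
                raise ValueError(f"duplicate tree node name {node.name!r}")
            names.add(node.name)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def bfs(self) -> Iterator[TreeNode]:
        queue = [self.root]
        while queue:
            node = queue.pop(0)
            yield node
            queue.extend(node.children)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.bfs() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


# -- cross-network scores ------------------------------------------------------


class ScoreStore:
    """Sparse symmetric store of cross-network similarity bit scores.

    Absence of an entry means "no hit above threshold".  Intra-network pairs
    are rejected: similarity scores only relate proteins of distinct networks.
    """

    def __init__(self) -> None:
        self._by_node: dict[str, dict[str, float]] = {}
        self._n_entries = 0

    def set(self, u: str, v: str, score: float) -> None:
        if network_of(u) == network_of(v):
            raise ValueError(f"intra-network score pair {u} -- {v}")
        if score <= 0:
            raise ValueError(f"bit score must be positive, got {score}")
        if v not in self._by_node.get(u, ()):
            self._n_entries += 1
        self._by_node.setdefault(u, {})[v] = score
        self._by_node.setdefault(v, {})[u] = score

    def get(self, u: str, v: str) -> Optional[float]:
        return self._by_node.get(u, {}).get(v)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        u, v = pair
        return v in self._by_node.get(u, ())

    def partners(self, u: str) -> dict[str, float]:
        """All scored partners of ``u`` (read-only view semantics)."""
        return self._by_node.get(u, {})

    def drop_node(self, u: str) -> None:
        for w in list(self._by_node.get(u, ())):
            del self._by_node[w][u]
            if not self._by_node[w]:
                del self._by_node[w]
            self._n_entries -= 1
        self._by_node.pop(u, None)

    def drop_network(self, network_id: str) -> None:
        prefix = network_id + "."
        for u in [n for n in self._by_node if n.startswith(prefix)]:
            self.drop_node(u)

    def items(self) -> Iterator[tuple[str, str, float]]:
        """Iterate entries once each, in deterministic sorted order."""
        for u in sorted(self._by_node, key=node_sort_key):
            for v in sorted(self._by_node[u], key=node_sort_key):
                if (network_of(u), node_sort_key(u)) < (network_of(v), node_sort_key(v)):
                    yield u, v, self._by_node[u][v]

    def __len__(self) -> int:
        return self._n_entries


@dataclass
class NetworkFamily:
    """A generated benchmark unit: leaf networks, scores, and ground truth."""

    networks: dict[str, PPINetwork]
    scores: ScoreStore
    fo: FOUniverse
    tree: Optional[PhyloTree] = None
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    internals: dict[str, PPINetwork] = field(default_factory=dict)

    def annotation_of(self, node_id: str) -> str:
        """Resolve a node ID to its FO label; raise ``KeyError`` if unknown."""
        net_id = network_of(node_id)
        pool = self.networks.get(net_id) or self.internals.get(net_id)
        if pool is None or node_id not in pool.annotation:
            raise KeyError(f"node {node_id!r} not found in family")
        return pool.annotation[node_id]

    def validate(self) -> list[str]:
        """Family-wide invariant check; returns violations (empty = pass)."""
        violations: list[str] = []
        for net in self.networks.values():
            violations.extend(validate(net))
        for u, v, _ in self.scores.items():
            for node in (u, v):
                try:
                    self.annotation_of(node)
                except KeyError:
                    violations.append(f"score entry references unknown node {node}")
        return violations
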