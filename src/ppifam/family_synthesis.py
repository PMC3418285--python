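"""Family synthesis: evolve an ancestral network along a phylogeny.

The generator builds one ancestral network (seed grown to ``ancestral_size``,
each new node founding its own FO group), then walks the binary phylogeny
breadth-first.  At each internal node the parent network *bifurcates*: both
children start as exact copies (inheriting annotations and every stored
score against previously created networks) and receive freshly drawn
similarity scores against each other.  Each child then *diverges* by growing
for as many steps as its branch length; a node added during divergence
inherits its source's FO group with probability ``p_f`` (else it is
unannotated), and inherits its source's similarity scores shrunk by a random
factor ``c ~ Uniform[c_min, 1]``.  Crystal-growth nodes that found a module
of their own have no source: they stay unannotated and receive no scores.

Branch lengths count nodes, so each leaf network's size is exactly
``ancestral_size`` plus the summed branch lengths on its root-to-leaf path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from ppifam.graph_core import (
    EVENT_DIV_NEW_MODULE,
    UNANNOTATED,
    FOUniverse,
    NetworkFamily,
    PhyloTree,
    PPINetwork,
    ScoreStore,
    copy_network,
)
from ppifam.growth_models import CG, GrowthParams, build_cg_seed, build_duplication_seed, grow
from ppifam.similarity_model import ScoreParams, assign_cross_scores, scale_inherited_scores


@dataclass
class SynthesisConfig:
    """Complete parameterization of a family-synthesis run."""

    ancestral_size: int = 1000
    growth: GrowthParams = field(default_factory=GrowthParams)
    scores: ScoreParams = field(default_factory=ScoreParams)
    p_f: float = 0.9
    keep_internal: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_f <= 1.0:
            raise ValueError("p_f must be in [0, 1]")
        if self.ancestral_size < 1:
            raise ValueError("ancestral_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SynthesisConfig":
        data = dict(data)
        growth = data.pop("growth", {})
        scores = data.pop("scores", {})
        return cls(
            growth=GrowthParams(**growth),
            scores=ScoreParams(**scores),
            **data,
        )


def synthesize_ancestor(
    config: SynthesisConfig,
    rng: np.random.Generator,
    fo: Optional[FOUniverse] = None,
    network_id: str = "R",
) -> PPINetwork:
    """Build the model-appropriate seed and grow it to ``ancestral_size``.

    Every node added during ancestral growth founds a fresh FO group.
    """
    if fo is None:
        fo = FOUniverse()
    if config.growth.model == CG:
        net = build_cg_seed(rng, fo=fo, network_id=network_id)
    else:
        net = build_duplication_seed(config.growth, rng, fo=fo, network_id=network_id)
    if config.ancestral_size < net.n_nodes:
        raise ValueError(
            f"ancestral_size {config.ancestral_size} is smaller than the "
            f"{net.n_nodes}-node seed"
        )
    grow(
        net,
        config.ancestral_size - net.n_nodes,
        config.growth,
        rng,
        annotation_policy="ancestral",
        fo=fo,
    )
    return net


def bifurcate(
    parent: PPINetwork,
    child_ids: tuple[str, str],
    scores: ScoreStore,
    config: SynthesisConfig,
    rng: np.random.Generator,
) -> tuple[PPINetwork, PPINetwork]:
    """Split a parent network into two child copies.

    Both children inherit, entry by entry, the parent's stored scores against
    all previously created networks (re-keyed to the child node IDs); fresh
    sibling scores between the two children are then drawn from the score
    model.  The parent's own score entries are removed from the store.
    """
    id_a, id_b = child_ids
    child_a = copy_network(parent, id_a)
    child_b = copy_network(parent, id_b)
    # inherit the parent's cross-network scores
    parent_entries = [
        (u, dict(scores.partners(u))) for u in parent.nodes_sorted()
    ]
    for u, partners in parent_entries:
        suffix = u.rpartition(".")[2]
        for w, s in partners.items():
            scores.set(f"{id_a}.{suffix}", w, s)
            scores.set(f"{id_b}.{suffix}", w, s)
    scores.drop_network(parent.network_id)
    # fresh sibling scores
    for u, w, s in assign_cross_scores(child_a, child_b, config.scores, rng):
        scores.set(u, w, s)
    return child_a, child_b


def diverge(
    net: PPINetwork,
    n_new: int,
    scores: ScoreStore,
    config: SynthesisConfig,
    rng: np.random.Generator,
) -> None:
    """Grow a child network by ``n_new`` nodes with inheritance, in place.

    Each added node with a source (duplication source for DMC/DMR, anchor
    for CG) inherits the source's FO group with probability ``p_f`` and the
    source's similarity scores scaled per entry by ``c ~ Uniform[c_min, 1]``.
    Sourceless nodes (CG new modules) stay unannotated and unscored.
    """
    log = grow(net, n_new, config.growth, rng, annotation_policy="deferred")
    for v, source, event in log:
        if source is None or event == EVENT_DIV_NEW_MODULE:
            net.annotation[v] = UNANNOTATED
            continue
        if rng.random() < config.p_f:
            net.annotation[v] = net.annotation[source]
        else:
            net.annotation[v] = UNANNOTATED
        inherited = scale_inherited_scores(
            dict(scores.partners(source)), config.scores, rng
        )
        for w, s in inherited.items():
            scores.set(v, w, s)


def synthesize_family(
    tree: PhyloTree,
    config: SynthesisConfig,
    seed: Optional[int] = None,
) -> NetworkFamily:
    """Generate a complete network family along a phylogeny.

    The tree is traversed breadth-first; each internal node's network is
    bifurcated into its two children, which are then diverged by their
    branch lengths.  The output holds the leaf networks (plus internal-node
    snapshots when ``keep_internal`` is set), the score store over all leaf
    pairs, and the FO ground truth.  Identical ``(tree, config, seed)``
    always reproduces the identical family.
    """
    tree.validate()
    rng_seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(rng_seed)
    fo = FOUniverse()
    scores = ScoreStore()
    internals: dict[str, PPINetwork] = {}

    root = tree.root
    active: dict[str, PPINetwork] = {
        root.name: synthesize_ancestor(config, rng, fo=fo, network_id=root.name)
    }

    queue = [root]
    while queue:
        node = queue.pop(0)
        if node.is_leaf:
            continue
        parent = active.pop(node.name)
        if config.keep_internal:
            internals[node.name] = parent
        left, right = node.children
        child_a, child_b = bifurcate(
            parent, (left.name, right.name), scores, config, rng
        )
        active[left.name] = child_a
        active[right.name] = child_b
        diverge(child_a, left.branch_length, scores, config, rng)
        diverge(child_b, right.branch_length, scores, config, rng)
        queue.extend(node.children)

    return NetworkFamily(
        networks=active,
        scores=scores,
        fo=fo,
        tree=tree,
        config=config.to_dict(),
        seed=rng_seed,
        internals=internals,
    )
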