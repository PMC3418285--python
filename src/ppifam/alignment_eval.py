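"""Scoring of predicted network alignments against the FO ground truth.

A predicted alignment is a set of *equivalence classes*: groups of node IDs
(from one or more networks) claimed to be functionally orthologous.  Before
scoring, unannotated nodes are removed from every class and classes of size
one are discarded.  A class is *correct* when all of its members share one
FO group.  Metrics:

* **SPE** (specificity): percentage of correct classes.
* **CN** (correct nodes): total membership of the correct classes.
* **MNE** (mean normalized entropy): per class, the Shannon entropy of its
  FO composition divided by ``log d`` (``d`` = number of distinct groups in
  the class; 0 when ``d`` = 1), averaged over classes.  Lower is better.
* **Coverage**: histogram of classes by the number of distinct networks
  represented.

Local alignments are merged into a global one by transitive closure: nodes
co-aligned anywhere end up in the same equivalence class.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Sequence

from ppifam.graph_core import UNANNOTATED, NetworkFamily, network_of

EquivalenceClassSet = list[set[str]]


def merge_local_alignments(pairings: Iterable[Iterable[str]]) -> EquivalenceClassSet:
    """Transitive closure over co-aligned node groups (union-find).

    Classes in the result are the connected components of the co-alignment
    graph, ordered by smallest member for determinism.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for group in pairings:
        members = list(group)
        for node in members:
            parent.setdefault(node, node)
        for other in members[1:]:
            ra, rb = find(members[0]), find(other)
            if ra != rb:
                parent[rb] = ra
    classes: dict[str, set[str]] = {}
    for node in parent:
        classes.setdefault(find(node), set()).add(node)
    return sorted(classes.values(), key=lambda c: min(c))


def preprocess(
    classes: Sequence[Iterable[str]], family: NetworkFamily
) -> EquivalenceClassSet:
    """Drop unannotated nodes from every class, then drop classes of size <= 1.

    Raises ``KeyError`` for node IDs that do not resolve against the family.
    """
    out: EquivalenceClassSet = []
    for cls in classes:
        kept = {n for n in cls if family.annotation_of(n) != UNANNOTATED}
        if len(kept) > 1:
            out.append(kept)
    return out


def _is_correct(cls: set[str], family: NetworkFamily) -> bool:
    labels = {family.annotation_of(n) for n in cls}
    return len(labels) == 1 and UNANNOTATED not in labels


def specificity(classes: EquivalenceClassSet, family: NetworkFamily) -> float:
    """Percentage of classes whose members all share one FO group."""
    if not classes:
        raise ValueError("specificity is undefined for zero equivalence classes")
    correct = sum(1 for cls in classes if _is_correct(cls, family))
    return 100.0 * correct / len(classes)


def correct_nodes(classes: EquivalenceClassSet, family: NetworkFamily) -> int:
    """Total number of nodes sitting in correct (pure) classes."""
    return sum(len(cls) for cls in classes if _is_correct(cls, family))


def normalized_entropy(cls: Iterable[str], family: NetworkFamily) -> float:
    """Entropy of a class's FO composition, normalized by ``log d``.

    With ``p_i`` the fraction of the class in FO group ``i`` and ``d`` the
    number of distinct groups: ``H = -(1/log d) * sum p_i log p_i``; a pure
    class (``d`` = 1) has entropy 0.
    """
    members = list(cls)
    if not members:
        raise ValueError("normalized entropy of an empty class is undefined")
    tally = Counter(family.annotation_of(n) for n in members)
    d = len(tally)
    if d == 1:
        return 0.0
    total = len(members)
    h = -sum((c / total) * math.log(c / total) for c in tally.values())
    return h / math.log(d)


def mean_normalized_entropy(
    classes: EquivalenceClassSet, family: NetworkFamily
) -> float:
    """Arithmetic mean of per-class normalized entropies, in [0, 1].

    (Benchmark tables often display this value multiplied by 100; the
    command-line interface offers that display mode.)
    """
    if not classes:
        raise ValueError("mean normalized entropy is undefined for zero classes")
    return sum(normalized_entropy(cls, family) for cls in classes) / len(classes)


def coverage(
    classes: EquivalenceClassSet, family: NetworkFamily
) -> dict[int, int]:
    """Number of classes spanning exactly k distinct networks, per k."""
    tally: Counter[int] = Counter()
    for cls in classes:
        tally[len({network_of(n) for n in cls})] += 1
    return dict(sorted(tally.items()))


def ground_truth_alignment(family: NetworkFamily) -> EquivalenceClassSet:
    """The perfect alignment implied by the FO ground truth.

    Groups every FO label's annotated nodes (across the family's leaf
    networks) into one class; singleton groups are kept here and removed by
    :func:`preprocess`.
    """
    by_label: dict[str, set[str]] = {}
    for net in family.networks.values():
        for node in net.nodes_sorted():
            label = net.annotation[node]
            if label != UNANNOTATED:
                by_label.setdefault(label, set()).add(node)
    return [by_label[label] for label in sorted(by_label)]
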