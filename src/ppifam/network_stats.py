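"""Statistics used to characterize networks and network pairs.

These operators implement the validation readouts for synthetic families:
the degree distribution P(k) (scale-free check), the clustering-coefficient
profile C(k) (hierarchical-modularity check), the potential-ortholog count
distribution F(n) for a network pair, and simple fitters for the power-law
exponent and Gamma score parameters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx
import numpy as np

from ppifam.graph_core import PPINetwork, ScoreStore, network_of


@dataclass
class DegreeProfile:
    """Empirical degree distribution: degree k -> fraction of nodes P(k)."""

    fractions: dict[int, float]


@dataclass
class ClusteringProfile:
    """Mean clustering coefficient per degree, for degrees >= 2."""

    means: dict[int, float]


@dataclass
class OrthologCountProfile:
    """Distribution of per-node potential-ortholog counts for a network pair.

    ``fractions[n]`` is the fraction of net_a's nodes with exactly ``n``
    scored partners (n >= 1); ``zero_fraction`` covers nodes with none.
    ``counts`` keeps the raw tallies for count-floored fitting.
    """

    fractions: dict[int, float]
    zero_fraction: float
    counts: dict[int, int] = field(default_factory=dict)


def degree_distribution(net: PPINetwork) -> DegreeProfile:
    """Exact empirical degree distribution of a non-empty network."""
    if net.n_nodes == 0:
        raise ValueError("degree distribution of an empty network is undefined")
    tally = Counter(d for _, d in net.graph.degree)
    n = net.n_nodes
    return DegreeProfile({k: c / n for k, c in sorted(tally.items())})


def clustering_profile(net: PPINetwork) -> ClusteringProfile:
    """Mean clustering coefficient C(k) per degree.

    The per-node coefficient is ``2 E_n / (k (k - 1))`` with ``E_n`` the edge
    count among the node's neighbors; nodes of degree < 2 are excluded (the
    coefficient is undefined there).
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    coeffs = nx.clustering(net.graph)
    for node, c in coeffs.items():
        k = net.graph.degree[node]
        if k < 2:
            continue
        sums[k] = sums.get(k, 0.0) + c
        counts[k] = counts.get(k, 0) + 1
    return ClusteringProfile({k: sums[k] / counts[k] for k in sorted(sums)})


def ortholog_count_profile(
    net_a: PPINetwork,
    net_b: PPINetwork,
    scores: ScoreStore,
    T: float = 0.0,
) -> OrthologCountProfile:
    """Distribution of H(v) = number of partners of v (in net_a) within net_b
    whose stored score is >= T."""
    b_id = net_b.network_id
    tally: Counter[int] = Counter()
    for v in net_a.nodes_sorted():
        h = sum(
            1
            for w, s in scores.partners(v).items()
            if network_of(w) == b_id and s >= T
        )
        tally[h] += 1
    n = net_a.n_nodes
    fractions = {k: c / n for k, c in sorted(tally.items()) if k >= 1}
    counts = {k: c for k, c in sorted(tally.items()) if k >= 1}
    return OrthologCountProfile(fractions, tally.get(0, 0) / n if n else 0.0, counts)


def fit_power_law_exponent(
    profile: Mapping[int, float],
    min_count_per_bin: int = 5,
    counts: Optional[Mapping[int, int]] = None,
) -> float:
    """Power-law exponent of a discrete profile by log-log least squares.

    Fits ``log f(n) = -gamma * log n + const`` over the support, optionally
    restricted to bins whose raw tally meets ``min_count_per_bin`` (pass
    ``counts``); returns ``gamma`` as a positive exponent.  Log-log linear
    regression is used (rather than an MLE) because log-log linearity is the
    criterion the profiles are judged by.
    """
    usable = [
        n
        for n, f in profile.items()
        if n >= 1
        and f > 0
        and (counts is None or counts.get(n, 0) >= min_count_per_bin)
    ]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 usable support points for a power-law fit, got {len(usable)}"
        )
    usable.sort()
    x = np.log(np.array(usable, dtype=float))
    y = np.log(np.array([profile[n] for n in usable], dtype=float))
    slope = float(np.polyfit(x, y, 1)[0])
    return -slope


def fit_gamma_moments(samples) -> tuple[float, float]:
    """Method-of-moments Gamma fit: shape = mean^2/var, scale = var/mean."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if var <= 0 or mean <= 0:
        raise ValueError("samples must have positive mean and variance")
    return mean * mean / var, var / mean
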