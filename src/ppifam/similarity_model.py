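"""Stochastic model of cross-network sequence-similarity scores.

Simulated scores live on the BLAST bit-score scale.  A pair of proteins in
two different networks draws its score from a Gamma distribution whose
parameters depend on the pair's true orthology status:

* same (non-sentinel) FO label:  ``Gamma(k_o, theta_o) + b``
* different labels / unannotated: ``Gamma(k_r, theta_r)``

where ``b`` is an optional bias separating the two distributions.  A score
below the threshold ``T`` is treated as a BLAST no-hit and not stored, which
reproduces the thresholding of real similarity searches.

Scores are sparse: each node draws its number of scored partners from a
truncated power law ``P(n) ~ n^-beta`` on ``1..n_max``, matching the
empirical potential-ortholog count distribution of real network pairs.
When a node arises by duplication during divergence, its scores are not
redrawn but inherited from its source, shrunk by a per-entry factor
``c ~ Uniform[c_min, 1]`` that models sequence-level drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from ppifam.graph_core import UNANNOTATED, PPINetwork

#: rejection attempts before falling back to inverse-CDF truncated sampling
_REJECTION_CAP = 1000


@dataclass
class ScoreParams:
    """Parameters of the similarity-score model.

    Defaults give an ortholog distribution ``Gamma(2, 50)`` (mean 100 bits),
    a non-ortholog distribution ``Gamma(2, 25)`` (mean 50 bits), a no-hit
    threshold of 40 bits, and a partner-count power law with exponent 1.7
    truncated at 100 — choices that put the simulated cross-network
    statistics in the ranges observed for real interactome pairs.
    """

    k_o: float = 2.0
    theta_o: float = 50.0
    k_r: float = 2.0
    theta_r: float = 25.0
    T: float = 40.0
    beta: float = 1.7
    n_max: int = 100
    bias_b: float = 0.0
    c_min: float = 0.9

    def __post_init__(self) -> None:
        for name in ("k_o", "theta_o", "k_r", "theta_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.T < 0:
            raise ValueError("threshold T must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.bias_b < 0:
            raise ValueError("bias_b must be >= 0")
        if not 0 < self.c_min <= 1:
            raise ValueError("c_min must be in (0, 1]")


def gamma_pdf(x: float, k: float, theta: float) -> float:
    """Density of the Gamma distribution with shape ``k`` and scale ``theta``."""
    if k <= 0 or theta <= 0:
        raise ValueError("shape and scale must be > 0")
    if x < 0:
        raise ValueError("x must be >= 0")
    return float(stats.gamma.pdf(x, a=k, scale=theta))


def _truncated_gamma_draw(
    k: float, theta: float, lower: float, rng: np.random.Generator, shift: float = 0.0
) -> float:
    """Draw ``Gamma(k, theta) + shift`` conditioned on the result being >= lower.

    Rejection sampling with a capped number of attempts, then an exact
    inverse-CDF fallback for extreme thresholds.
    """
    for _ in range(_REJECTION_CAP):
        x = rng.gamma(k, theta) + shift
        if x >= lower:
            return float(x)
    f_lower = stats.gamma.cdf(lower - shift, a=k, scale=theta)
    u = rng.uniform(f_lower, 1.0)
    return float(stats.gamma.ppf(u, a=k, scale=theta) + shift)


def sample_pair_score(
    same_fo: bool, params: ScoreParams, rng: np.random.Generator
) -> Optional[float]:
    """Draw one pair score; return ``None`` (no hit) if it falls below ``T``."""
    if same_fo:
        x = rng.gamma(params.k_o, params.theta_o) + params.bias_b
    else:
        x = rng.gamma(params.k_r, params.theta_r)
    return float(x) if x >= params.T else None


def _powerlaw_pmf(beta: float, n_max: int) -> np.ndarray:
    weights = np.arange(1, n_max + 1, dtype=float) ** (-beta)
    return weights / weights.sum()


def sample_ortholog_count(params: ScoreParams, rng: np.random.Generator) -> int:
    """Draw a partner count ``n`` in ``1..n_max`` with ``P(n) ~ n^-beta``."""
    pmf = _powerlaw_pmf(params.beta, params.n_max)
    return int(rng.choice(params.n_max, p=pmf)) + 1


def assign_cross_scores(
    net_a: PPINetwork,
    net_b: PPINetwork,
    params: ScoreParams,
    rng: np.random.Generator,
) -> list[tuple[str, str, float]]:
    """Generate fresh similarity scores between two networks.

    Every node on *each* side draws a target partner count from the
    truncated power law; pairing then proceeds in two stages so that the
    realized per-node counts follow the target distribution on both sides:

    1. same-FO pairs (true orthologs) are created first, in random order,
       while both endpoints still have remaining capacity;
    2. remaining capacity is turned into "stubs" on each side, the two stub
       lists are shuffled and matched up (a bipartite configuration model);
       collisions with existing pairs are skipped and surplus stubs on the
       longer side are dropped.

    Each created pair receives a Gamma score matching its true orthology
    status, redrawn until it clears ``T`` — selected pairs are exactly the
    stored hits.
    """
    pmf = _powerlaw_pmf(params.beta, params.n_max)
    a_nodes = net_a.nodes_sorted()
    b_nodes = net_b.nodes_sorted()
    cap_a = dict(
        zip(a_nodes, (rng.choice(params.n_max, size=len(a_nodes), p=pmf) + 1))
    )
    cap_b = dict(
        zip(b_nodes, (rng.choice(params.n_max, size=len(b_nodes), p=pmf) + 1))
    )

    def draw(ortholog: bool) -> float:
        if ortholog:
            return _truncated_gamma_draw(
                params.k_o, params.theta_o, params.T, rng, shift=params.bias_b
            )
        return _truncated_gamma_draw(params.k_r, params.theta_r, params.T, rng)

    entries: dict[tuple[str, str], float] = {}

    # stage 1: true-ortholog pairs first, capacity permitting
    fo_b = net_b.fo_index()
    same_pairs = [
        (u, w)
        for u in a_nodes
        if net_a.annotation[u] != UNANNOTATED
        for w in fo_b.get(net_a.annotation[u], ())
    ]
    rng.shuffle(same_pairs)
    for u, w in same_pairs:
        if cap_a[u] > 0 and cap_b[w] > 0:
            entries[(u, w)] = draw(ortholog=True)
            cap_a[u] -= 1
            cap_b[w] -= 1

    # stage 2: bipartite stub matching of the remaining capacity
    stubs_a = [u for u in a_nodes for _ in range(int(cap_a[u]))]
    stubs_b = [w for w in b_nodes for _ in range(int(cap_b[w]))]
    rng.shuffle(stubs_a)
    rng.shuffle(stubs_b)
    for u, w in zip(stubs_a, stubs_b):
        if (u, w) in entries:
            continue
        ortholog = (
            net_a.annotation[u] != UNANNOTATED
            and net_a.annotation[u] == net_b.annotation[w]
        )
        entries[(u, w)] = draw(ortholog)
    return [(u, w, entries[(u, w)]) for u, w in sorted(entries)]


def scale_inherited_scores(
    source_scores: dict[str, float],
    params: ScoreParams,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Scores of a duplicate node derived from its source's entries.

    Each entry is shrunk by an independent factor ``c ~ Uniform[c_min, 1]``;
    entries falling below the threshold are dropped (the duplicate has
    diverged past detectability for that partner).
    """
    out: dict[str, float] = {}
    for partner in sorted(source_scores):
        c = rng.uniform(params.c_min, 1.0)
        s = c * source_scores[partner]
        if s >= params.T:
            out[partner] = s
    return out


def bit_to_evalue(
    score: float, query_len: int = 500, db_len: int = 200_000_000
) -> float:
    """BLAST E-value of a bit score: ``E = m * n * 2^(-S)``.

    Defaults correspond to querying a 500-residue protein against a database
    of 2x10^8 residues.
    """
    if score < 0:
        raise ValueError("bit score must be >= 0")
    if query_len < 1 or db_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    return float(query_len) * float(db_len) * math.pow(2.0, -score)
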