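# Methods

`ppifam` generates families of evolutionarily related synthetic
protein–protein interaction (PPI) networks along a user-supplied phylogeny,
together with a ground-truth functional-orthology (FO) labelling and a
sparse matrix of simulated sequence-similarity bit scores. The families are
intended as benchmarks for network alignment algorithms, which are scored
against the known orthology.

## The generative model

### Growth of a single network

Three single-network growth operators are implemented. Each adds exactly one
node per step:

* **DMC** (duplication–mutation–complementation). A uniformly chosen node
  `u` is duplicated: the new node `v` copies `u`'s full neighborhood. For
  each neighbor `w`, one of the two edges `u–w` / `v–w` is chosen uniformly
  to be at risk and deleted with probability `q_del` (default 0.7); finally
  `u–v` is added with probability `q_con` (default 0.1).
* **DMR** (duplication with random mutation). As DMC, but each copied edge
  is deleted independently with probability `q_del` (default 0.59), and `v`
  is attached to each node not adjacent to `u` (excluding `u` and `v`)
  independently with probability `q_new / N` (default `q_new` = 0.24, `N` =
  network size before the step).
* **CG** (crystal growth). Modules are detected by fast-greedy
  (Clauset–Newman–Moore) modularity agglomeration. A new node founds its own
  module with probability `p_new` (default 0.1), wiring `m` edges (default
  2) network-wide by the anti-preferential rule (candidate weight
  `1/(degree+1)`); otherwise a module is chosen uniformly, an anchor is
  drawn anti-preferentially inside it (redrawn up to 10 times until it has
  at least `m` neighbors, then a fallback connects to the anchor and all its
  neighbors), and the new node connects to the anchor plus `m − 1` of its
  neighbors, joining the anchor's module. Connecting to the anchor itself is
  a deliberate design choice: every selected neighbor then closes a triangle
  with the anchor, which is what gives crystal growth its characteristic
  dense, module-centred clustering — wiring only to the anchor's neighbors
  leaves the 2000-node clustering profile at essentially zero. Modules are
  recomputed every `round(0.1 · N)` steps (configurable), i.e. every step
  early on and only occasionally in large networks.

Seeds: the duplication-based models start from a 50-node network containing
a 10-clique (FO group F1), a 7-clique (F2), 5 random inter-clique bridge
edges, and 33 peripheral nodes each attached to one uniformly chosen clique
node and carrying a singleton FO group (F3…F35). CG starts from a 4-cycle
with one fresh group per node. During ancestral growth every new node founds
a fresh FO group.

The DMC probability defaults were calibrated so that 2000-node DMC networks
show log–log-linear degree distributions with fitted exponents ≈ 1.6–1.9,
adjacent to the 1.8–2.3 range reported for real interactomes. Published
fits of these growth models quote a wide spread of probability values, so
the defaults here are the package's own calibration and are fully exposed
in configuration.

### Family synthesis

The phylogeny is a rooted binary tree whose integer branch lengths count
the nodes added along that branch. The ancestor (root network, size
`ancestral_size`) is grown from the seed, then the tree is traversed
breadth-first. At each internal node:

1. **Bifurcation** — the parent network is copied into the two children
   (node IDs re-prefixed, integer suffixes preserved, so counterparts are
   recoverable by suffix). Both children inherit the parent's stored scores
   against all previously created networks entry-by-entry, and fresh
   sibling scores are drawn between the two children.
2. **Divergence** — each child grows by its branch length. A new node with
   a source (duplication source, or CG anchor) inherits the source's FO
   group with probability `p_f` (default 0.9) and otherwise becomes
   unannotated; its similarity scores are the source's entries shrunk by
   independent factors `c ~ Uniform[c_min, 1]` (default `c_min` = 0.9),
   with entries falling below the threshold dropped. CG nodes that found a
   new module have no source: they stay unannotated and receive no scores.

Leaf node counts therefore satisfy, exactly, `ancestral_size` plus the sum
of branch lengths on the root-to-leaf path.

### Similarity scores

Scores mimic BLAST bit scores. A scored pair draws from `Gamma(k_o, θ_o) + b`
when the two nodes share a (non-sentinel) FO label and `Gamma(k_r, θ_r)`
otherwise (defaults: `k_o=2, θ_o=50, k_r=2, θ_r=25, b=0`). Scores below the
threshold `T` (default 40 bits) are no-hits and never stored. The bias `b`
separates the two distributions for sensitivity experiments; increasing it
raises the ortholog mean and leaves the background untouched. Bit scores
convert to E-values as `E = m·n·2^(−S)` with defaults `m = 500` residues,
`n = 2×10⁸` residues.

Cross-network scores are sparse. Every node on **both** sides of a network
pair draws a target partner count from a truncated power law
`P(n) ∝ n^(−β)` on `1..n_max` (defaults β = 1.7, `n_max` = 100). Pairing is
two-stage: true-ortholog (same-FO) pairs are created first, in random
order, while both endpoints have remaining capacity; the remaining capacity
becomes "stubs" on each side, and the two shuffled stub lists are matched
up (a bipartite configuration model; collisions are skipped and surplus
stubs dropped). This construction makes the *realized* per-node partner
counts follow the target law on both sides simultaneously — a one-sided
"each node picks n partners" scheme run in both directions and unioned
inflates every count with a Poisson background and destroys the power law
(measured exponent ≈ 0.34 instead of ≈ 1.5–1.7). Pair scores are drawn
truncated at `T` (rejection sampling capped at 1000 attempts, then an exact
inverse-CDF fallback), since selected pairs are by construction the hits.

## Evaluation metrics

A predicted alignment is a list of equivalence classes (groups of node
IDs). Preprocessing removes unannotated nodes from every class and then
discards classes of size ≤ 1. A class is *correct* when all members share
one FO group. Reported metrics: specificity (SPE, % correct classes),
correct nodes (CN, total membership of correct classes), mean normalized
entropy (MNE, per-class Shannon entropy of the FO composition divided by
`log d` with `d` the number of distinct groups — 0 for pure classes —
averaged over classes; the library reports the raw [0, 1] value, the CLI
can display ×100 as benchmark tables conventionally do), and coverage (a
histogram of classes by number of distinct networks spanned). Local
alignments are merged into a global one by union-find transitive closure.

## Benchmark presets

* `pairwise` — two leaves of 3,000 and 4,000 nodes (ancestor 2,000,
  branches 1,000/2,000; only the leaf sizes are fixed by the published
  suite — the ancestor/branch split is this package's documented choice
  satisfying the size identity).
* `5way` — caterpillar phylogeny with five leaves at depths 1,2,3,4,4,
  every branch 500, ancestor 1,000 → leaves 1500/2000/2500/3000/3000
  (distantly related species).
* `8way` — full binary tree, eight leaves, every branch 200, ancestor 400
  → eight 1,000-node leaves (closely related species; the 400 is derived
  from the printed leaf size minus three branches of 200).

## Numerical and reproducibility choices

All randomness flows through one `numpy.random.Generator` consumed in
traversal order; node iteration is always sorted (network label, then
integer suffix), and module detection rebuilds its graph in sorted order, so
a `(tree, config, seed)` triple regenerates a byte-identical family. File
writers emit sorted rows; floats are serialized with shortest round-trip
`repr`. Entropy uses natural logarithms (the base cancels against `log d`).
Degrees < 2 are excluded from the clustering profile rather than scored 0
(the coefficient is undefined there). Power-law exponents are fitted by
log–log least squares over bins meeting a count floor (default 5), because
log–log linearity is the criterion the profiles are judged by, not
likelihood fit quality.

## What the generator does and does not emulate

Generated families reproduce: scale-free-like degree profiles, decreasing
clustering profiles for DMC and CG (DMR is known to be weaker on
modularity), sparse potential-ortholog counts with a power-law profile
(fitted exponent ≈ 1.4–1.6 on the pairwise shape, inside the 1.4–2.1 range
observed between real interactome pairs), overlapping ortholog /
non-ortholog score distributions, and exact size accounting.

Not modeled: gene loss (nodes are never deleted), edge rewiring between
bifurcation and growth, actual sequences or alignments (only score
statistics), directed/weighted interactions, and assay biases of real
interactome screens (spoke/matrix artifacts, study bias). Passing tests on
these synthetic families therefore demonstrates self-consistency of the
model and correct bookkeeping of the ground truth — not that an aligner
scoring well here will score well on noisy experimental data.

Known limitation: deep divergence (branch lengths several times the
ancestral size) inflates partner counts through chained duplication
inheritance and flattens the realized potential-ortholog exponent to ≈ 1.2;
the partner-count law is enforced exactly only at bifurcation time.

## Problem sizes used in the test and acceptance suites

Statistical properties are checked on 2000-node grown networks, the
pairwise-shape family (3000/4000 leaves), and small two-leaf families;
annotation-inheritance recovery uses ≈ 2,600 conditioned duplication events.
These sizes give stable statistics (binomial 3σ ≈ 0.017 for the
inheritance-rate check) while keeping the default suite fast.
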