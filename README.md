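# ppifam

Synthetic families of evolutionarily related protein–protein interaction
(PPI) networks, with ground-truth orthology — a benchmark generator for
network alignment algorithms, plus the metrics to score alignments against
the generated truth.

## The problem

Network aligners (IsoRank-style spectral methods, local seed-and-extend
aligners, progressive phylogeny-guided aligners, …) predict groups of
functionally orthologous proteins across the PPI networks of several
species. Evaluating them on real data is circular: the "true" orthology is
itself inferred from sequence. `ppifam` instead *generates* families of
networks whose complete evolutionary history — and therefore whose
functional orthology — is known exactly, so alignment accuracy can be
measured against an unambiguous gold standard.

## The model

A single ancestral network G₀ of N₀ nodes is grown from a small seed with
one of three growth models: **DMC** (duplication–mutation–
complementation), **DMR** (duplication with random mutation), or **CG**
(crystal growth, module-oriented). The ancestor then evolves along a rooted
binary phylogeny T traversed breadth-first: at each internal node the
network bifurcates into two copies, and each copy diverges by growing for
as many steps as its branch length (branch lengths count nodes, so each
leaf has exactly N₀ + Σ branch lengths on its root-to-leaf path nodes).

Every node carries a functional-orthology (FO) label φ(v): ancestral nodes
found their own groups; a node duplicated during divergence inherits its
source's group with probability P_f (else it becomes unannotated, φ(v)=∅).
Cross-network similarity scores s(u, v) mimic BLAST bit scores: pairs with
the same FO label draw from Γ(k_o, θ_o) + b, others from Γ(k_r, θ_r);
scores below a threshold T are no-hits. Per-node scored-partner counts are
enforced to follow a power law P(n) ∝ n^(−β), as observed between real
interactomes, and duplicates inherit their source's scores shrunk by
c ~ Uniform[c_min, 1]. Predicted alignments (equivalence classes of node
IDs) are scored by specificity (SPE), correct nodes (CN), mean normalized
entropy (MNE) and coverage.

See `docs/methods.md` for the full model, parameter defaults, and design
rationale.

## Worked example

Generate a two-leaf family (1,000-node ancestor, 500 nodes added per
branch), then score the ground-truth-derived perfect alignment against it:

```sh
$ printf '(A:500,B:500)R;\n' > tree.nwk
$ ppifam generate --tree tree.nwk --out fam --ancestral-size 1000 \
      --model DMC --seed 42
wrote family to fam (model=DMC, seed=42)
leaf sizes: A=1500, B=1500
```

The family directory holds plain TSV: per-network edge lists
(`A.edges.tsv`), node annotations (`A.nodes.tsv`: node, FO label or `-`,
lineage), per-pair scores (`A__B.sim.tsv`), the tree, and the full config
snapshot. Build the perfect alignment from the truth and evaluate it:

```python
from ppifam.io_cli import read_family, write_alignment
from ppifam.alignment_eval import ground_truth_alignment, preprocess

fam = read_family("fam")
classes = preprocess(ground_truth_alignment(fam), fam)
write_alignment(classes, "truth.aln")
```

```sh
$ ppifam eval fam truth.aln --mne-x100
classes 985
SPE     100.00
CN      2887
MNE     0.00
coverage[2]     985
```

Reading: 985 equivalence classes survive preprocessing (unannotated nodes
removed, singletons dropped); all are pure (SPE 100), they contain 2,887
correctly grouped proteins, their mean normalized entropy is 0 (perfect
functional consistency), and every class spans both networks. A real
aligner's cluster-per-line output is evaluated the same way; `--merge-local`
first merges overlapping local alignments by transitive closure.

Benchmark suites matching the published shapes (`pairwise`: 3,000/4,000
leaves; `5way`: 1500–3000 caterpillar; `8way`: eight 1,000-node leaves):

```sh
ppifam benchmark 5way --out suites --model DMC --seed 7
ppifam stats suites/5way_DMC --out profiles   # P(k), C(k), F(n) tables
ppifam validate suites/5way_DMC               # invariant check
```

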