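# aceforest

Ancestral gene-content reconstruction over *co-evolving forests*: a set of
phylogenetic trees (one per gene family) sharing a single rooted binary
topology, linked by co-evolution edges between nodes of different trees that
correspond to the same organism. Every edge — tree or co-evolution — carries
a 2×2 weight table over the label pairs 00/01/10/11, and the goal is a 0/1
labeling of all nodes (ancestral states plus missing extant entries)
minimizing the total edge weight.

## Features

- **Exact solvers** — vectorized brute-force oracle, weighted-parsimony
  dynamic programming over the product alphabet of each co-evolutionary
  component, and an FPT solver that enumerates labels only at nodes incident
  to anti-correlated ("red") edges and solves the residual correlated
  ("green") problem by min-cut.
- **Graph reductions** — green-only instances ((0,a,a,0) tables) reduce to
  minimum cut, solved via max-flow with observed leaves as terminals;
  red-only instances ((a,0,0,a) tables) correspond to min-UnCut, verified by
  enumeration on small instances.
- **LP / IP / QP** — the linear-programming relaxation (4·|E|+|V| variables,
  3·|E| constraints) and its integer counterpart via HiGHS; the relaxed
  optimum is a certified lower bound and is integral on green-only inputs.
  A multilinear quadratic objective with coordinate descent is included.
- **Heuristics** — steepest single-flip greedy improvement, a
  cluster/DP/greedy scheme for oversized components, and a min-cut-seeded
  heuristic that rounds green tables to (0,A,A,0).
- **Dominant co-evolutionary set (DCES)** — select a subset of gene families
  from which the rest of a target genome can be imputed: families outside
  the set must be covered either by mutual information to set members
  (residual H − ΣI below W1) or by their own tree signal (above W2);
  imputation alternates ancestral inference with local flips.
- **Synthetic data** — a seeded generator of forests with coupled family
  pairs (correlated or anti-correlated, with analytic stationary joint
  tables), per-branch gain/loss, and missing leaf entries, plus genome
  masking for imputation benchmarks.

## CLI

```sh
# generate a synthetic forest (Newick + TSVs + ground truth)
aceforest simulate --organisms 20 --families 50 --couples 10 \
    --strength 0.8 --seed 7 --out data/

# solve: brute | dp | fpt | mincut | lp | ip | heuristic | mincut-heuristic
aceforest solve --tree data/tree.nwk --profiles data/profiles.tsv \
    --coevo-edges data/coevo_edges.tsv --tree-tables data/tree_tables.tsv \
    --method dp --out results/

# score an existing labeling
aceforest score --tree data/tree.nwk --profiles data/profiles.tsv \
    --coevo-edges data/coevo_edges.tsv --labels results/labels.tsv

# dominant-set selection + genome imputation for one organism
aceforest dces --tree data/tree.nwk --profiles data/profiles.tsv \
    --coevo-edges data/coevo_edges.tsv --target org0 \
    --w1 0.3 --w2 1.0 --out dces_out/
```

Exit codes: 0 success, 2 input error, 3 size-cap exceeded.

### File formats (all plain text)

- `tree.nwk` — one shared Newick topology; unnamed internal nodes are
  auto-named `n<preorder index>`.
- `profiles.tsv` — rows = families, columns = organism (leaf) names,
  cells `0`/`1`/`?`.
- `coevo_edges.tsv` — `family_i  family_j  w00  w01  w10  w11`; if absent,
  edges are derived from profile mutual information above `--mi-floor`.
- `tree_tables.tsv` — per-edge tables keyed by child node name; if absent,
  every tree edge uses the unit table (0,1,1,0).

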