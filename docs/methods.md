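# Methods

## The reconstruction model

`ccinet` treats cell-cell interaction discovery as directed link prediction
on a spatial contact graph. The observed graph is built purely from
geometry: for each cell, its `k = 3` nearest neighbours whose Euclidean
distance does not exceed a global cutoff are direct contacts, and any pair
nominated by either member becomes an (undirected) contact. The cutoff
defaults to the 95th percentile of the distribution of per-cell 3rd-nearest-
neighbour distances (`--knn-percentile`); the idea is that the bulk of 3-NN
distances reflects genuine physical contact spacing while the upper tail
belongs to cells at tissue margins or tears. There is no closed-form
justification for the exact percentile — it is one interpretable knob, and
edge counts are monotone in it.

Every cell gets a sender embedding and a receiver embedding. One directed
convolution layer updates the sender channel by aggregating receiver
embeddings over out-edges of the normalised adjacency
`Â = (D̃⁺)^{-β} Ã (D̃⁻)^{-α}`, and the receiver channel symmetrically
through `Âᵀ`; both updates read the *input* embeddings (simultaneous, not
Gauss-Seidel, update — the two channels are peers). The encoder stacks two
such layers with a ReLU between and a linear outer layer. The decoder is
the asymmetric inner product `A′[i,j] = σ(⟨z_S(i), z_T(j)⟩)`; no
symmetrisation is applied at any point, which is what lets the model express
direction even though the training graph is symmetric.

In heterogeneous mode each weight matrix becomes a per-cell-type stack and
node `j`'s row is transformed by its own type's matrix before aggregation.
With one type (or identical per-type matrices) this reproduces the
homogeneous forward pass bit-for-bit, because the homogeneous path applies
weights before aggregation too — the two implementations share the same
floating-point operation order.

## Training

The objective is mean binary cross-entropy over observed contacts (label 1)
and an equal number of non-adjacent ordered pairs (label 0), resampled fresh
every epoch by rejection sampling that excludes all known positive edges.
Held-out test edges are removed from the message-passing adjacency during
training; otherwise the encoder would see the very edges it is evaluated on.

Defaults, with reasons:

| parameter | default | why |
|---|---|---|
| hidden / latent dims | 64 / 32 | small panels (≤ a few hundred genes); larger dims overfit |
| α, β | 0.5 / 0.5 | symmetric degree normalisation, the GCN convention |
| self loops | on | keeps isolated cells finite and wires each cell's own expression into its codes |
| optimiser | Adam, lr 0.01 | standard for graph autoencoders of this size |
| epochs | 200 | loss plateaus well before this on all tested sizes |
| weight decay | 0.01 | without it the encoder overfits uninformative genes, which blurs permutation-sensitivity scores |
| input scaling | per-gene z-score | raw softplus-scale expression produces huge initial inner products; the decoder saturates and training collapses to p ≈ 0.5. The scaler is fitted at training time and stored on the model, so re-encoding shuffled inputs reuses it |

Zero out-/in-degrees contribute a normalisation factor of 1 rather than a
division by zero. Edge probabilities are clipped to `[1e-7, 1 − 1e-7]`
inside the loss. The threshold comparison for predicted edges is inclusive
(`A′ ≥ t`), so a zero model at `t = 0.5` predicts every off-diagonal pair —
a documented boundary convention. Dense `A′` materialisation is refused
above 20 000 cells; use `score_pairs` on candidate pairs instead.

A single base seed drives everything: per-stage seeds are derived as
`SeedSequence([base, stage_index, …])` reduced below 2³¹ (see
`ccinet.metrics.derive_seed`), so one integer reproduces a whole run,
including every replicate of a robustness scan.

## Perturbation protocol

Five manipulations probe robustness, all pure functions of input + seed:
multiplicative noise `X·2^r` with `r ~ N(0, σ)` per entry (Gaussian on the
log2 scale; zeros stay zero), random removal of undirected contacts (both
orientations together; the removed contacts become held-out positives with
an equal number of sampled non-edges as negatives), whole-gene dropout, and
exact-quota zeroing of nonzero values. Fractional quotas round half-even so
counts are exact and testable. The fifth manipulation replaces the shared
initialisation `S⁰ = T⁰ = X` with ligand-gene and receptor-gene expression
submatrices; the first-layer weight shapes follow each side's own width.
Gene matching against the ligand-receptor table is case-sensitive exact
match by default (a case-folding flag exists) to avoid silent cross-species
symbol aliasing.

The robustness scan runs perturb → split → train → evaluate `n_reps` times
per level with derived seeds, and compares each level's AUROC replicates to
unperturbed baseline replicates with a *two-sided Welch* t-test (replicate
variances differ across levels, so no pooled-variance assumption). Two
degenerate conventions: exactly tied replicate sets report p = 1; zero
variance in both groups with different means reports p = 0.

## Downstream analyses

**Cell-type enrichment.** Observed directed edge counts per ordered type
pair are compared to a null built by permuting the cell-type labels over
nodes with the topology fixed (1000 permutations by default), which
preserves the degree structure exactly; a degree-preserving edge-target
rewiring null is available as an alternative. P-values use the add-one
convention `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so the smallest
attainable p is `1/(n_perm+1)` and p = 0 is impossible. Pairs with
`p < α` form the grouped arrow-diagram export.

**Sensitivity scores.** A gene's score is ΔAUROC = baseline − shuffled
AUROC, where "shuffled" permutes that gene's column across cells and
re-scores the *fixed* test split with the *frozen* trained weights,
averaged over 30 repeats. Re-scoring (rather than retraining per shuffle)
is the default because 30 repeats × all genes × retraining is
computationally disproportionate and adds optimiser noise on top of shuffle
noise; `retrain=True` is available. A constant gene scores exactly 0 (every
permutation is a no-op). Ligand-receptor pairs are scored the same way with
both columns permuted in the same repeat (independent permutations per
column — "shuffled at the same time" fixes the repeat, not the
permutation), after a co-expression filter: each gene nonzero in at least
10% (`co_expr_fraction`) of the relevant cells.

## The synthetic-tissue generator

The generator exists so every claim above is testable without downloads. It
emulates: (1) even, tissue-like cell spacing — uniform positions plus one
Monte-Carlo Lloyd relaxation step; (2) spatially organised cell types — a
mixture of a uniform draw and a Voronoi-partition draw weighted by
`type_spatial_clustering`; (3) type expression programs — a shared baseline
plus per-type elevated marker blocks; (4) spatial autocorrelation — each
contact edge owns a latent factor added to both endpoints (scaled by
`neighbor_coupling` and normalised by √degree), so adjacent cells literally
share expression components and adjacency is learnable; (5) directional
signalling — every cell of a designated sender type has its ligand-block
genes raised and its graph out-neighbours get raised receptor-block genes,
giving an unambiguous planted direction; (6) technical corruption —
Gaussian noise before a softplus link and per-entry Bernoulli dropout
(defaults 0.3 and 0.1, FISH-like levels). An optional negative-binomial
count mode exists; the default real-valued output matches FISH-style
normalised inputs. Two extra knobs support controlled experiments:
`n_null_genes` appends pure-noise columns (negative controls for
sensitivity), and `n_coupled_genes` restricts the shared-neighbour factor to
a designated block so individual "signature" genes carry enough signal to be
detectable by single-gene permutation.

What the generator does **not** emulate: platform-specific artefacts
(segmentation errors, bleed-through, spot mixing), realistic gene-gene
correlation structure beyond the planted factors, or 3-D geometry. Passing
tests therefore demonstrate that the implementation recovers *planted*
structure of the stated kinds at the stated noise levels — not performance
on any particular real platform.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale: structure
recovery at 1000 cells × 100 genes (5 seeds), degradation scans at 600
cells with 3 replicates per level, sensitivity recovery at 600 cells × 30
genes, directionality at 500 cells (5 seeds). These sizes keep a full run
in minutes on one CPU while leaving the measured effects (AUROC ≈ 0.9,
clear degradation trends, 4–5/5 direction wins) far from their decision
thresholds.

## Known limitations

- The distance-threshold rule is a percentile stand-in; the contact-calling
  literature it follows describes the construction qualitatively, not as a
  formula.
- Directionality is only identifiable through asymmetric inputs (planted
  blocks, ligand/receptor initialisation); with `S⁰ = T⁰ = X` on a
  symmetric graph, forward and reverse scores differ only through learned
  asymmetry with no ground truth to prefer either.
- The heterogeneous encoder multiplies parameters by the number of types;
  on small synthetic tissues it does not reliably beat the homogeneous one
  (it needs genuinely type-distinct interaction patterns and enough cells
  per type).
- Training is full-batch dense-feature numpy; it is comfortable to a few
  thousand cells and a few hundred genes, beyond which per-epoch cost and
  the dense feature matrix dominate.
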