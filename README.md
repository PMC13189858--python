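# ccinet — directed cell-cell interaction networks from spatial transcriptomics

Single-cell spatial transcriptomics measures each cell's expression profile
together with its position in the tissue. Cells in direct physical contact
are far more likely to interact than distant ones, so the geometry defines a
*partial*, undirected cell-cell interaction (CCI) network — the contacts we
can see. `ccinet` learns from that incomplete network and the expression
matrix to reconstruct a **complete, directed** interaction network: which
cell pairs communicate, and in which direction the signal flows. It is aimed
at computational biologists analysing seqFISH/MERFISH-scale panels or
high-throughput platforms, without requiring a curated ligand-receptor
database (though one can be plugged in).

## Model

Cells form a graph `G(A, X)` with expression matrix `X ∈ R^{N×M}` and
adjacency `A` built from coordinates: each cell's 3 nearest neighbours
within a global distance cutoff (a percentile of the 3-NN distance
distribution) are direct contacts. Every cell `i` carries **two** latent
embeddings — a sender code `z_S(i)` and a receiver code `z_T(i)` — learned
by a two-layer directed graph convolution encoder on the degree-normalised
adjacency `Â = (D̃⁺)^{-β} Ã (D̃⁻)^{-α}` (with `Ã = A + I`):

```
Z_S = Â · ReLU(Âᵀ S⁰ W_S⁰) · W_T¹        S⁰ = T⁰ = X
Z_T = Âᵀ · ReLU(Â T⁰ W_T⁰) · W_S¹
```

An asymmetric inner-product decoder scores every *ordered* cell pair:

```
A′[i, j] = σ(⟨z_S(i), z_T(j)⟩)
```

Because `Z_S ≠ Z_T`, `A′` need not be symmetric — the decoder can express
direction. With cell-type labels the encoder becomes a heterogeneous graph
convolution: each weight matrix is replaced by a per-type stack applied
row-wise by each node's type. Training minimises binary cross-entropy on
observed contacts versus resampled non-adjacent pairs (Adam, weight decay,
per-gene z-scored inputs; held-out test edges are masked from message
passing).

On top of the reconstruction the package provides:

- **Robustness scans** — fold-change expression noise (`X·2^r`,
  `r ~ N(0,σ)`), random edge removal, gene dropout and value dropout, each
  with replicated retraining and a Welch t-test against baseline;
- **Cell-type enrichment** — permutation test (1000 label shuffles, add-one
  p-values) for which ordered type pairs interact above chance;
- **Sensitivity scores** — ΔAUROC after permuting one gene's (or one
  ligand-receptor pair's) expression across cells, averaged over 30
  shuffles, ranking the genes the reconstruction depends on;
- **Ligand/receptor initialisation** — `S⁰` from ligand and `T⁰` from
  receptor expression (CellChatDB-style table), which seeds the sender and
  receiver channels with directional biology;
- **A synthetic-tissue generator** with planted spatial, type and
  directional structure, so everything above is testable offline.

## Worked example

```bash
python examples/01_simulate_and_reconstruct.py
```

```
tissue: 500 cells x 80 genes, 893 direct contacts
held-out AUROC   0.9484
held-out AUPRC   0.9417
held-out F1      0.8663
held-out Accuracy   0.8708
```

10% of contacts were hidden during training; an AUROC of 0.95 means those
hidden contacts receive far higher edge probability than random non-adjacent
pairs — adjacency was recoverable from expression alone. The other examples
(`examples/02…05`) walk through the robustness scan, enrichment, gene
sensitivity, and directional ligand-receptor reconstruction; each prints a
short interpretation of its numbers.

The same pipeline runs from the shell:

```bash
ccinet simulate --n-cells 500 --n-genes 80 --seed 0 --out-dir data/
ccinet run --expr data/expression.csv --coords data/coords.csv \
           --types data/types.csv --seed 1 --out-dir out/
ccinet enrich --edges out/edges.tsv --types data/types.csv --out enrich.csv
```

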