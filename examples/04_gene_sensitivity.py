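"""Rank genes by how much the reconstruction relies on them.

Plants a tissue where only 5 genes carry the neighbour-coupling signal and 5
trailing genes are pure noise, then scores every gene by delta-AUROC: the
drop in held-out AUROC after permuting that gene's expression across cells
(30 shuffles, trained weights frozen).
"""

import numpy as np

from ccinet import SyntheticConfig, generate_dataset, split_edges, train
from ccinet.analysis import all_gene_sensitivity

config = SyntheticConfig(n_cells=600, n_genes=30, n_types=3,
                         signal_genes_per_type=3, n_coupled_genes=5,
                         neighbor_coupling=3.0, n_null_genes=5,
                         ligand_block=(), receptor_block=(), seed=0)
dataset, graph, truth = generate_dataset(config)
split = split_edges(graph, 0.2, seed=1)
model = train(dataset, split, epochs=150, seed=2)

report = all_gene_sensitivity(model, dataset, split, n_repeats=30, seed=3)
print(f"baseline AUROC {report.baseline_auroc:.4f}")
print(report.table.head(10).to_string(index=False))

ranks = {g: r for r, g in enumerate(report.table["feature"], start=1)}
coupled_ranks = [ranks[f"gene_{j}"] for j in truth["coupled_genes"]]
null_ranks = [ranks[f"gene_{j}"] for j in truth["null_genes"]]
print(f"\nmean rank of planted coupled genes: {np.mean(coupled_ranks):.1f}")
print(f"mean rank of pure-noise genes:      {np.mean(null_ranks):.1f}")
print("Coupled genes carry the adjacency signal, so shuffling them costs "
      "AUROC and they rank higher (smaller rank) than pure-noise columns.")
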