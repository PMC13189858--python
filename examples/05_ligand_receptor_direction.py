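"""Directional signalling from ligand/receptor-restricted initialisation.

The generator plants a sender cell type whose ligand-block genes are high and
whose graph neighbours carry high receptor-block expression. Initialising the
sender embeddings S from ligand expression and the receiver embeddings T from
receptor expression lets the asymmetric decoder score the planted
sender -> receiver direction above its reverse.
"""

import numpy as np
import pandas as pd

from ccinet import SyntheticConfig, generate_dataset, split_edges, train
from ccinet.perturb import LigandReceptorTable, lr_initialize
from ccinet.analysis import lr_pair_sensitivity

config = SyntheticConfig(n_cells=500, seed=0)
dataset, graph, truth = generate_dataset(config)

ligands = [f"gene_{j}" for j in truth["ligand_block"]]
receptors = [f"gene_{j}" for j in truth["receptor_block"]]
table = LigandReceptorTable(pd.DataFrame({
    "ligand": ligands, "receptor": receptors,
    "category": ["Cell-Cell Contact"] * len(ligands)}))

S0, T0, lig_found, rec_found = lr_initialize(dataset, table)
print(f"S initialised from {len(lig_found)} ligand genes, "
      f"T from {len(rec_found)} receptor genes")

split = split_edges(graph, 0.1, seed=1)
model = train(dataset, split, S0=S0, T0=T0, epochs=200, seed=2)

senders = set(truth["sender_cells"])
directed = np.array([e for e in truth["directed_edges"] if e[1] not in senders])
fwd = model.score_pairs(directed).mean()
back = model.score_pairs(directed[:, ::-1]).mean()
print(f"mean A'[sender->receiver] {fwd:.4f}")
print(f"mean A'[receiver->sender] {back:.4f}")
print("The forward direction scoring higher shows the asymmetric decoder "
      "recovered the planted direction of signalling.")

# pair sensitivity runs on a standard all-genes model (the shuffled full
# transcriptome is re-encoded, so the encoder must accept all genes)
full_model = train(dataset, split, epochs=150, seed=4)
report, diag = lr_pair_sensitivity(full_model, dataset, split, table,
                                   n_repeats=10, seed=3)
print("\nL-R pair sensitivity (delta-AUROC, both columns shuffled):")
print(report.table.head(5).to_string(index=False))
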