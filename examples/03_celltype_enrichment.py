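"""Which cell-type pairs interact more than chance in a reconstructed network?

Trains the autoencoder, thresholds the reconstructed edge probabilities, and
runs the label-permutation enrichment test: observed directed edge counts per
ordered type pair against 1000 label shuffles (topology fixed).
"""

import numpy as np

from ccinet import (
    SyntheticConfig, generate_dataset, split_edges, train,
    predict_interactions, celltype_enrichment, export_grouped_network,
)

config = SyntheticConfig(n_cells=400, seed=0, type_spatial_clustering=0.9)
dataset, graph, _ = generate_dataset(config)
split = split_edges(graph, 0.1, seed=1)
model = train(dataset, split, epochs=100, seed=2)

result = predict_interactions(model, threshold=0.9)
print(f"{len(result.predicted_edges)} directed edges at threshold 0.9")

enrich = celltype_enrichment(result.predicted_edges, dataset.cell_types,
                             n_perm=1000, seed=3)
grouped = export_grouped_network(enrich, alpha=0.05)
print(grouped.to_string(index=False))
print("\nEach row is an ordered type pair whose edge count exceeds the "
      "permutation null at p < 0.05; spatially segregated types interact "
      "mostly within themselves, so the diagonal pairs dominate.")
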