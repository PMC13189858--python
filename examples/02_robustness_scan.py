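"""Scan reconstruction quality against increasing expression noise.

Applies multiplicative fold-change noise (2^r, r ~ N(0, sigma)) at several
sigma levels, retrains from scratch a few times per level, and reports the
mean held-out AUROC with a Welch t-test against unperturbed baseline runs.
"""

from ccinet import SyntheticConfig, generate_dataset
from ccinet.metrics import robustness_scan

config = SyntheticConfig(n_cells=400, seed=0)
dataset, graph, _ = generate_dataset(config)

scan = robustness_scan(dataset, graph, kind="noise",
                       levels=[0.0, 1.0, 2.0, 3.0], n_reps=3, base_seed=0,
                       train_kwargs=dict(epochs=100))
print(scan.summary().to_string(index=False))
print("\nmean_auroc should decay as sigma grows; 'significant' marks levels "
      "whose replicates differ from baseline at p < 0.05 (Welch t-test).")
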