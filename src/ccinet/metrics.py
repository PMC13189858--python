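"""Link-prediction metrics and the robustness scan protocol.

Reconstruction quality is scored on held-out contacts versus sampled
non-adjacent pairs with four metrics: AUROC, AUPRC, F1 and Accuracy. The
robustness scan repeats perturb-train-evaluate ``n_reps`` times per
perturbation level and flags the levels whose replicate metrics differ
significantly from unperturbed baseline replicates (two-sided Welch t-test,
alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from . import model as model_mod
from . import perturb as perturb_mod
from .graph import CellGraph, EdgeSplit, SpatialDataset, split_edges

METRICS = ("auroc", "auprc", "f1", "accuracy")


class UndefinedMetricError(ValueError):
    """Both classes must be present to compute ranking metrics."""


@dataclass
class EvalRecord:
    auroc: float
    auprc: float
    f1: float
    accuracy: float
    n_pos: int
    n_neg: int
    threshold_used: float

    def as_dict(self) -> Dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def evaluate_links(scores: np.ndarray, labels: np.ndarray,
                   threshold: float = 0.5) -> EvalRecord:
    """Score a binary edge classification.

    AUROC uses the rank statistic with midranks for ties (all-tied scores
    give 0.5); AUPRC is the step-integrated precision-recall area; F1 and
    Accuracy binarise at ``threshold`` (inclusive).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("labels contain a single class")
    pred = (scores >= threshold).astype(int)
    return EvalRecord(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, pred, zero_division=0.0)),
        accuracy=float(accuracy_score(labels, pred)),
        n_pos=n_pos, n_neg=n_neg, threshold_used=threshold,
    )


def evaluate_split(model, split: EdgeSplit, threshold: float = 0.5) -> EvalRecord:
    """Evaluate a trained model on a held-out edge split."""
    pos = np.asarray(split.test_pos).reshape(-1, 2)
    neg = np.asarray(split.test_neg).reshape(-1, 2)
    scores = np.concatenate([model.score_pairs(pos), model.score_pairs(neg)])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return evaluate_links(scores, labels, threshold=threshold)


def derive_seed(base_seed: int, *indices: int) -> int:
    """Documented per-stage seed derivation: SeedSequence(base, idx...) -> int < 2^31."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value with the exact-tie p = 1 convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(np.sort(a), np.sort(b)) or (
        a.std() == 0 and b.std() == 0 and a.mean() == b.mean()
    ):
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):
        # zero variance in both groups but different means: maximal evidence
        return 0.0
    return p


@dataclass
class RobustnessScan:
    """Per-level replicate metrics with Welch t-test significance vs baseline."""

    kind: str
    levels: List[float]
    records: pd.DataFrame  # columns: level, rep, auroc, auprc, f1, accuracy
    baseline: pd.DataFrame  # columns: rep, auroc, auprc, f1, accuracy
    alpha: float = 0.05

    def summary(self, metric: str = "auroc") -> pd.DataFrame:
        base = self.baseline[metric].to_numpy()
        rows = []
        for level in self.levels:
            vals = self.records.loc[self.records["level"] == level, metric].to_numpy()
            p = welch_p(vals, base) if len(vals) >= 2 and len(base) >= 2 else np.nan
            rows.append({
                "level": level,
                f"mean_{metric}": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "p_value": p,
                "significant": bool(p < self.alpha) if np.isfinite(p) else False,
            })
        return pd.DataFrame(rows)

    def to_csv(self, records_path, summary_path, metric: str = "auroc") -> None:
        self.records.to_csv(records_path, index=False)
        self.summary(metric).to_csv(summary_path, index=False)

    def plot(self, path, metric: str = "auroc") -> None:
        """Optional line plot of metric vs perturbation level."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        s = self.summary(metric)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.errorbar(s["level"], s[f"mean_{metric}"], yerr=s["sd"], marker="o")
        ax.set_xlabel(f"{self.kind} level")
        ax.set_ylabel(metric.upper())
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _run_once(dataset: SpatialDataset, graph: CellGraph, kind: str,
              level: float, seed: int, train_kwargs: dict) -> EvalRecord:
    """One perturb -> split -> train -> evaluate cycle."""
    tk = dict(train_kwargs)
    test_fraction = tk.pop("test_fraction", 0.1)
    X = dataset.X
    g = graph
    if kind == "noise" and level > 0:
        X = perturb_mod.add_noise(X, level, seed=derive_seed(seed, 1))
    elif kind == "genes" and level > 0:
        X, _ = perturb_mod.dropout_genes(X, level, seed=derive_seed(seed, 1))
    elif kind == "values" and level > 0:
        X = perturb_mod.dropout_values(X, level, seed=derive_seed(seed, 1))

    ds = SpatialDataset(
        X=X, coords=dataset.coords,
        gene_names=np.array([f"g{j}" for j in range(X.shape[1])], dtype=object)
        if X.shape[1] != dataset.n_genes else dataset.gene_names,
        cell_ids=dataset.cell_ids, cell_types=dataset.cell_types,
    )

    if kind == "edges" and level > 0:
        removal = perturb_mod.remove_edges(graph, level, seed=derive_seed(seed, 2))
        # train on the surviving contacts; recover the removed ones
        kept = removal.graph.undirected_contacts()
        removed = removal.removed_contacts
        split = EdgeSplit(
            train_pos=np.vstack([kept, kept[:, ::-1]]),
            test_pos=np.vstack([removed, removed[:, ::-1]]),
            test_neg=removal.matched_negatives,
            test_fraction=level, seed=seed,
        )
    else:
        split = split_edges(g, test_fraction=test_fraction,
                            seed=derive_seed(seed, 3))
    model = model_mod.train(ds, split, seed=derive_seed(seed, 4), **tk)
    return evaluate_split(model, split)


def robustness_scan(
    dataset: SpatialDataset,
    graph: CellGraph,
    kind: str,
    levels: Sequence[float],
    n_reps: int = 5,
    base_seed: int = 0,
    alpha: float = 0.05,
    train_kwargs: Optional[dict] = None,
) -> RobustnessScan:
    """Perturb-train-evaluate replicates over a grid of perturbation levels.

    ``kind`` is one of 'noise' (fold-change sigma), 'edges' (removal
    fraction), 'genes' (gene dropout fraction), 'values' (nonzero dropout
    fraction). Each level is run ``n_reps`` times with distinct derived
    seeds; an unperturbed baseline is run the same number of times, and each
    level's AUROC replicates are compared to the baseline replicates with a
    two-sided Welch t-test.
    """
    if kind not in ("noise", "edges", "genes", "values"):
        raise ValueError(f"unknown perturbation kind {kind!r}")
    levels = sorted(float(v) for v in levels)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_reps < 2:
        import warnings

        warnings.warn("n_reps < 2: t-test undefined, p-values reported as NaN")
    train_kwargs = train_kwargs or {}

    base_rows = []
    for rep in range(n_reps):
        rec = _run_once(dataset, graph, kind, 0.0,
                        derive_seed(base_seed, 10_000, rep), train_kwargs)
        base_rows.append({"rep": rep, **rec.as_dict()})

    rows = []
    for li, level in enumerate(levels):
        for rep in range(n_reps):
            rec = _run_once(dataset, graph, kind, level,
                            derive_seed(base_seed, li, rep), train_kwargs)
            rows.append({"level": level, "rep": rep, **rec.as_dict()})

    return RobustnessScan(
        kind=kind, levels=list(levels),
        records=pd.DataFrame(rows), baseline=pd.DataFrame(base_rows),
        alpha=alpha,
    )
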