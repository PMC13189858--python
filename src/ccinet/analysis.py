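"""Downstream biology on the reconstructed interaction network.

Three analyses interpret a trained reconstruction: (1) permutation enrichment
of directed interactions between cell-type pairs, comparing observed edge
counts to a null built by shuffling cell-type labels over nodes with the
topology fixed; (2) per-gene sensitivity scores, the mean drop in held-out
AUROC (delta-AUROC) after permuting one gene's expression across cells,
repeated 30 times; (3) the same shuffle-and-rescore protocol applied to
ligand-receptor gene pairs, both columns permuted in the same repeat.

Sensitivity scoring keeps the trained weights frozen and only re-encodes the
shuffled input (re-training per shuffle is available via ``retrain=True`` but
is far more expensive and noisier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import model as model_mod
from .graph import EdgeSplit, SpatialDataset, ValidationError
from .metrics import derive_seed
from .perturb import LigandReceptorTable


class EmptyResultError(ValueError):
    """A filter removed every candidate; diagnostics attached."""

    def __init__(self, message: str, diagnostics: Optional[pd.DataFrame] = None):
        super().__init__(message)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# cell-type enrichment

@dataclass
class EnrichmentResult:
    """Observed vs null interaction counts per ordered cell-type pair.

    ``p_value`` uses the add-one convention p = (1 + #{null >= obs}) /
    (1 + n_perm), so the smallest attainable p is 1/(n_perm + 1).
    """

    table: pd.DataFrame  # type_a, type_b, observed_count, null_mean, null_sd, p_value
    n_permutations: int
    seed: int
    null: str = "label"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def celltype_enrichment(
    predicted_edges: np.ndarray,
    cell_types: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
    null: str = "label",
) -> EnrichmentResult:
    """Permutation test for enrichment of interactions between cell types.

    Observed counts of directed edges are tallied per ordered type pair
    (within-type rows included). The null keeps the edge topology fixed and
    permutes the cell-type labels over nodes ``n_perm`` times ('label',
    default, preserves the degree structure exactly); ``null='rewire'``
    instead permutes edge targets among edges, preserving every node's in-
    and out-degree.
    """
    edges = np.asarray(predicted_edges, dtype=np.int64).reshape(-1, 2)
    labels = np.asarray(cell_types)
    if any(t is None or (isinstance(t, float) and np.isnan(t)) for t in labels):
        raise ValidationError("cell_types has missing values")
    if edges.size and edges.max() >= len(labels):
        raise ValidationError("edge endpoint without a cell-type label")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if null not in ("label", "rewire"):
        raise ValueError(f"unknown null model {null!r}")

    uniq = np.unique(labels)
    K = len(uniq)
    lut = {t: i for i, t in enumerate(uniq)}
    codes = np.array([lut[t] for t in labels], dtype=np.int64)

    def count_matrix(c: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        out = np.zeros((K, K), dtype=np.int64)
        np.add.at(out, (c[src], c[dst]), 1)
        return out

    src, dst = edges[:, 0], edges[:, 1]
    observed = count_matrix(codes, src, dst)

    rng = np.random.default_rng(seed)
    null_counts = np.zeros((n_perm, K, K), dtype=np.int64)
    for p in range(n_perm):
        if null == "label":
            null_counts[p] = count_matrix(rng.permutation(codes), src, dst)
        else:
            null_counts[p] = count_matrix(codes, src, rng.permutation(dst))

    ge = (null_counts >= observed[None]).sum(axis=0)
    pvals = (1.0 + ge) / (1.0 + n_perm)
    rows = []
    for a in range(K):
        for b in range(K):
            rows.append({
                "type_a": uniq[a], "type_b": uniq[b],
                "observed_count": int(observed[a, b]),
                "null_mean": float(null_counts[:, a, b].mean()),
                "null_sd": float(null_counts[:, a, b].std(ddof=0)),
                "p_value": float(pvals[a, b]),
            })
    return EnrichmentResult(table=pd.DataFrame(rows), n_permutations=n_perm,
                            seed=seed, null=null)


def export_grouped_network(enrichment: EnrichmentResult, alpha: float = 0.05
                           ) -> pd.DataFrame:
    """Grouped-edge table of significantly enriched ordered type pairs.

    One row per ordered type pair with p < alpha: (source_type, target_type,
    edge_count, p_value), ready for arrow-diagram rendering. ``alpha = 1``
    exports every pair (p-values never exceed 1).
    """
    t = enrichment.table
    keep = t if alpha >= 1.0 else t[t["p_value"] < alpha]
    return pd.DataFrame({
        "source_type": keep["type_a"].to_numpy(),
        "target_type": keep["type_b"].to_numpy(),
        "edge_count": keep["observed_count"].to_numpy(),
        "p_value": keep["p_value"].to_numpy(),
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# sensitivity scoring

@dataclass
class SensitivityReport:
    """Per-feature mean/sd delta-AUROC over shuffle repeats, sorted descending."""

    table: pd.DataFrame  # feature, mean_delta_auroc, sd_delta_auroc, n_repeats
    baseline_auroc: float
    deltas: Dict[str, np.ndarray] = field(default_factory=dict)

    def top(self, n: int) -> pd.DataFrame:
        if n > len(self.table):
            warnings.warn(
                f"requested top {n} but only {len(self.table)} features scored"
            )
        return self.table.head(n)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def write_gene_list(self, path, n: int) -> None:
        """Plain-text top-N feature list (one symbol per line)."""
        with open(path, "w") as fh:
            for f in self.top(n)["feature"]:
                fh.write(f"{f}\n")


def _test_arrays(split: EdgeSplit) -> Tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(split.test_pos).reshape(-1, 2)
    neg = np.asarray(split.test_neg).reshape(-1, 2)
    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return pairs, labels


def _score_auroc(model, split: EdgeSplit, S0: np.ndarray,
                 T0: Optional[np.ndarray] = None) -> float:
    pairs, labels = _test_arrays(split)
    Z = model.encode(S0, T0)
    scores = model.score_pairs(pairs, Z=Z)
    return float(roc_auc_score(labels, scores))


def gene_sensitivity(
    model,
    dataset: SpatialDataset,
    split: EdgeSplit,
    gene: str,
    n_repeats: int = 30,
    seed: int = 0,
    retrain: bool = False,
    train_kwargs: Optional[dict] = None,
) -> Tuple[float, float, np.ndarray]:
    """Delta-AUROC sensitivity of the reconstruction to one gene.

    Per repeat, the gene's expression column is permuted across cells, the
    modified matrix is re-encoded (weights frozen), the fixed test split is
    re-scored, and delta-AUROC = baseline - shuffled AUROC. Returns
    ``(mean, sd, per-repeat deltas)``; sd is reported as 0.0 when
    ``n_repeats == 1``. A constant gene yields exactly 0.
    """
    j = dataset.gene_index(gene)
    baseline = _score_auroc(model, split, dataset.X)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_repeats)
    for r in range(n_repeats):
        perm = rng.permutation(dataset.n_cells)
        if retrain:
            Xs = dataset.X.copy()
            Xs[:, j] = Xs[perm, j]
            ds = SpatialDataset(X=Xs, coords=dataset.coords,
                                gene_names=dataset.gene_names,
                                cell_ids=dataset.cell_ids,
                                cell_types=dataset.cell_types)
            m = model_mod.train(ds, split, mode=model.mode,
                                seed=derive_seed(seed, r),
                                **(train_kwargs or {}))
            pairs, labels = _test_arrays(split)
            auroc = float(roc_auc_score(labels, m.score_pairs(pairs)))
        else:
            Xs = dataset.X.copy()
            Xs[:, j] = Xs[perm, j]
            auroc = _score_auroc(model, split, Xs)
        deltas[r] = baseline - auroc
    sd = float(deltas.std(ddof=1)) if n_repeats > 1 else 0.0
    return float(deltas.mean()), sd, deltas


def all_gene_sensitivity(
    model,
    dataset: SpatialDataset,
    split: EdgeSplit,
    n_repeats: int = 30,
    seed: int = 0,
    genes: Optional[Sequence[str]] = None,
) -> SensitivityReport:
    """Sensitivity scores for every gene (or a subset), ranked descending.

    Each gene gets its own derived seed, so scores are independent of the
    iteration order.
    """
    genes = list(dataset.gene_names) if genes is None else list(genes)
    baseline = _score_auroc(model, split, dataset.X)
    rows, deltas = [], {}
    for g in genes:
        j = dataset.gene_index(g)
        mean, sd, d = gene_sensitivity(
            model, dataset, split, g, n_repeats=n_repeats,
            seed=derive_seed(seed, j),
        )
        rows.append({"feature": g, "mean_delta_auroc": mean,
                     "sd_delta_auroc": sd, "n_repeats": n_repeats})
        deltas[g] = d
    table = pd.DataFrame(rows).sort_values(
        "mean_delta_auroc", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return SensitivityReport(table=table, baseline_auroc=baseline, deltas=deltas)


def lr_pair_sensitivity(
    model,
    dataset: SpatialDataset,
    split: EdgeSplit,
    lr_table: LigandReceptorTable,
    cell_type_pair: Optional[Tuple[str, str]] = None,
    n_repeats: int = 30,
    seed: int = 0,
    co_expr_fraction: float = 0.1,
    category: Optional[str] = None,
) -> Tuple[SensitivityReport, pd.DataFrame]:
    """Delta-AUROC sensitivity of ligand-receptor pairs, with co-expression filtering.

    A pair is retained when both genes are present in the dataset and each is
    expressed (nonzero) in at least ``co_expr_fraction`` of the relevant
    cells — ligand in the sender type's cells and receptor in the receiver
    type's when ``cell_type_pair`` is given, otherwise across all cells. Per
    repeat, both columns are permuted (independent permutations drawn in the
    same repeat), the input is re-encoded and re-scored. Returns the ranked
    report plus a diagnostics table listing excluded pairs and reasons.
    """
    pairs = lr_table.pairs(category)
    gene_set = set(map(str, dataset.gene_names))

    if cell_type_pair is not None:
        if dataset.cell_types is None:
            raise ValueError("cell_type_pair given but dataset has no cell types")
        mask_a = dataset.cell_types == cell_type_pair[0]
        mask_b = dataset.cell_types == cell_type_pair[1]
        if not mask_a.any() or not mask_b.any():
            raise ValueError(f"cell types {cell_type_pair} not found")
    else:
        mask_a = mask_b = np.ones(dataset.n_cells, dtype=bool)

    def expressed_fraction(gene: str, mask: np.ndarray) -> float:
        col = dataset.X[mask, dataset.gene_index(gene)]
        return float((col != 0).mean())

    retained, diag = [], []
    for lig, rec in pairs:
        if lig not in gene_set or rec not in gene_set:
            diag.append({"ligand": lig, "receptor": rec,
                         "reason": "gene absent from dataset"})
            continue
        fl = expressed_fraction(lig, mask_a)
        fr = expressed_fraction(rec, mask_b)
        if fl < co_expr_fraction or fr < co_expr_fraction:
            diag.append({"ligand": lig, "receptor": rec,
                         "reason": f"co-expression below {co_expr_fraction} "
                                   f"(ligand {fl:.3f}, receptor {fr:.3f})"})
            continue
        retained.append((lig, rec))
    diagnostics = pd.DataFrame(diag, columns=["ligand", "receptor", "reason"])
    if not retained:
        raise EmptyResultError(
            "no ligand-receptor pair survives the co-expression filter",
            diagnostics,
        )

    baseline = _score_auroc(model, split, dataset.X)
    rows, deltas = [], {}
    for lig, rec in retained:
        jl, jr = dataset.gene_index(lig), dataset.gene_index(rec)
        rng = np.random.default_rng(derive_seed(seed, jl, jr))
        d = np.empty(n_repeats)
        for r in range(n_repeats):
            Xs = dataset.X.copy()
            Xs[:, jl] = Xs[rng.permutation(dataset.n_cells), jl]
            Xs[:, jr] = Xs[rng.permutation(dataset.n_cells), jr]
            d[r] = baseline - _score_auroc(model, split, Xs)
        name = f"{lig}->{rec}"
        rows.append({"feature": name, "mean_delta_auroc": float(d.mean()),
                     "sd_delta_auroc": float(d.std(ddof=1)) if n_repeats > 1 else 0.0,
                     "n_repeats": n_repeats})
        deltas[name] = d
    table = pd.DataFrame(rows).sort_values(
        "mean_delta_auroc", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    report = SensitivityReport(table=table, baseline_auroc=baseline, deltas=deltas)
    return report, diagnostics
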