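"""Robustness perturbations of expression and adjacency inputs.

Five manipulations probe how much corrupted input the reconstruction can
tolerate: multiplicative fold-change noise (2^r with r ~ N(0, sigma), i.e.
Gaussian on the log2 scale), random removal of contact edges, whole-gene
dropout, nonzero-value dropout, and restriction of the encoder inputs to
ligand/receptor gene panels. All perturbations are pure functions of their
inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .graph import CellGraph, SpatialDataset, sample_negative_pairs

CATEGORIES = ("Cell-Cell Contact", "Secreted Signaling", "ECM")
_CATEGORY_ALIASES = {
    "cell-cell contact": "Cell-Cell Contact",
    "secreted signaling": "Secreted Signaling",
    "ecm": "ECM",
    "extra cellular matrix": "ECM",
    "extracellular matrix": "ECM",
    "ecm-receptor": "ECM",
}


class EmptyPanelError(ValueError):
    """No ligand or receptor genes from the table are present in the data."""


@dataclass(frozen=True)
class PerturbationConfig:
    """Bundle of perturbation magnitudes for a robustness run."""

    noise_sigma: float = 0.0
    edge_removal_fraction: float = 0.0
    gene_dropout_fraction: float = 0.0
    value_dropout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("edge_removal_fraction", "gene_dropout_fraction",
                     "value_dropout_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class LigandReceptorTable:
    """Ligand/receptor gene pairs with interaction categories.

    Tabular layout: one row per (ligand_gene, receptor_gene, category), with
    category one of 'Cell-Cell Contact', 'Secreted Signaling', 'ECM'
    (common aliases such as 'Extracellular Matrix' are normalised).
    """

    table: pd.DataFrame
    source: str = ""

    def __post_init__(self):
        df = self.table.copy()
        df.columns = [c.lower() for c in df.columns]
        required = {"ligand", "receptor", "category"}
        if not required <= set(df.columns):
            raise ValueError(f"L-R table needs columns {sorted(required)}")
        df["category"] = [
            _CATEGORY_ALIASES.get(str(c).strip().lower(), str(c).strip())
            for c in df["category"]
        ]
        bad = set(df["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown L-R categories: {sorted(bad)}")
        if (df["ligand"].astype(str).str.len() == 0).any() or \
           (df["receptor"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene names in L-R table")
        if df.duplicated(subset=["ligand", "receptor"]).any():
            raise ValueError("duplicate ligand-receptor pairs")
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, source: str = "") -> "LigandReceptorTable":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        return cls(pd.read_csv(path, sep=sep), source=source or str(path))

    def filtered(self, category: Optional[str] = None) -> pd.DataFrame:
        if category is None:
            return self.table
        cat = _CATEGORY_ALIASES.get(category.strip().lower(), category)
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return self.table[self.table["category"] == cat]

    def pairs(self, category: Optional[str] = None) -> List[Tuple[str, str]]:
        df = self.filtered(category)
        return list(zip(df["ligand"].astype(str), df["receptor"].astype(str)))


# ---------------------------------------------------------------------------

def add_noise(X: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Multiplicative fold-change noise: X * 2^r, r ~ N(0, sigma) per entry.

    Equivalent to adding N(0, sigma) noise on the log2 scale; zeros stay
    exactly zero and non-negativity is preserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    X = np.asarray(X, dtype=float)
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    r = rng.normal(0.0, sigma, size=X.shape)
    return X * np.exp2(r)


@dataclass
class EdgeRemovalResult:
    """Reduced graph plus the held-out contacts and matched non-edges."""

    graph: CellGraph
    removed_contacts: np.ndarray  # (R, 2) unordered pairs
    matched_negatives: np.ndarray  # (2R, 2) ordered non-adjacent pairs


def remove_edges(graph: CellGraph, fraction: float, seed: int = 0
                 ) -> EdgeRemovalResult:
    """Randomly delete a fraction of undirected contacts.

    Both orientations of a removed contact disappear together, so the reduced
    graph stays symmetric. The removed contacts are returned as held-out
    positives together with an equal number (counting orientations) of
    originally non-existent ordered pairs as matched negatives.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    contacts = graph.undirected_contacts()
    rng = np.random.default_rng(seed)
    n_remove = _round_half_even(fraction * len(contacts))
    if n_remove == 0:
        return EdgeRemovalResult(
            graph=CellGraph(graph.n_nodes, graph.edges.copy(),
                            graph.self_loops_added),
            removed_contacts=np.empty((0, 2), dtype=np.int64),
            matched_negatives=np.empty((0, 2), dtype=np.int64),
        )
    order = rng.permutation(len(contacts))
    removed = contacts[order[:n_remove]]
    kept = contacts[order[n_remove:]]
    reduced = CellGraph.from_contacts(graph.n_nodes, kept)
    negatives = sample_negative_pairs(
        graph.n_nodes, 2 * n_remove, graph.edge_set(), rng
    )
    return EdgeRemovalResult(graph=reduced, removed_contacts=removed,
                             matched_negatives=negatives)


def _round_half_even(x: float) -> int:
    """Banker's rounding for fractional quotas (exact, testable counts)."""
    return int(np.rint(x))


def dropout_genes(X: np.ndarray, fraction: float, seed: int = 0
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Remove whole gene columns uniformly at random.

    Returns the reduced matrix and the sorted indices of kept genes; the
    number removed is round-half-even(fraction * n_genes).
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    n_drop = _round_half_even(fraction * m)
    if n_drop >= m:
        raise ValueError("gene dropout would remove every gene")
    rng = np.random.default_rng(seed)
    dropped = rng.choice(m, size=n_drop, replace=False)
    kept = np.setdiff1d(np.arange(m), dropped)
    return X[:, kept].copy(), kept


def dropout_values(X: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Zero an exact quota of nonzero entries, chosen uniformly.

    Exactly round-half-even(fraction * #nonzero) nonzero entries are set to
    zero, without replacement; existing zeros are untouched.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    X = np.asarray(X, dtype=float).copy()
    nz_rows, nz_cols = np.nonzero(X)
    n_zero = _round_half_even(fraction * len(nz_rows))
    if n_zero == 0:
        return X
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(nz_rows), size=n_zero, replace=False)
    X[nz_rows[pick], nz_cols[pick]] = 0.0
    return X


def lr_initialize(
    dataset: SpatialDataset,
    lr_table: LigandReceptorTable,
    category: Optional[str] = None,
    case_insensitive: bool = False,
) -> Tuple[np.ndarray, np.ndarray, List[str], List[str]]:
    """Ligand/receptor expression submatrices for encoder initialisation.

    Returns ``(S0, T0, ligand_genes, receptor_genes)``: S0 columns are the
    expression of the (deduplicated) ligand genes found in the dataset and T0
    the receptor genes, optionally restricted to one interaction category.
    Gene matching is case-sensitive exact match by default.
    """
    df = lr_table.filtered(category)
    if case_insensitive:
        lut = {str(g).lower(): i for i, g in enumerate(dataset.gene_names)}
        find = lambda g: lut.get(str(g).lower())
    else:
        lut = {str(g): i for i, g in enumerate(dataset.gene_names)}
        find = lambda g: lut.get(str(g))

    def panel(col: str) -> Tuple[List[str], List[int]]:
        names, idx, seen = [], [], set()
        for g in df[col].astype(str):
            j = find(g)
            if j is None or j in seen:
                continue
            seen.add(j)
            names.append(str(dataset.gene_names[j]))
            idx.append(j)
        return names, idx

    lig_names, lig_idx = panel("ligand")
    rec_names, rec_idx = panel("receptor")
    if not lig_idx or not rec_idx:
        missing = sorted(
            set(df["ligand"].astype(str)) - set(map(str, dataset.gene_names))
        ) + sorted(
            set(df["receptor"].astype(str)) - set(map(str, dataset.gene_names))
        )
        raise EmptyPanelError(
            f"no {'ligand' if not lig_idx else 'receptor'} genes found in the "
            f"dataset; missing symbols include {missing[:10]}"
        )
    S0 = dataset.X[:, lig_idx].copy()
    T0 = dataset.X[:, rec_idx].copy()
    return S0, T0, lig_names, rec_names
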