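"""Spatial inputs and the direct-contact cell adjacency graph.

Cells observed on a tissue section are nodes; a pair of cells is linked when
they are close enough to be in direct physical contact. The contact rule is:
for each cell, its ``k`` nearest neighbours (default 3) that lie within a
global distance threshold are contacts, and the union of all such pairs,
symmetrised, forms the adjacency matrix ``A``. The threshold itself is taken
as a percentile of the distribution of k-th nearest-neighbour distances.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread
from scipy.spatial import cKDTree


class AlignmentError(ValueError):
    """Row counts or cell identifiers of input files disagree."""


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


class FormatError(ValueError):
    """Unrecognised file extension."""


class InsufficientDataError(ValueError):
    """Too few cells or edges for the requested operation."""


@dataclass
class SpatialDataset:
    """Expression matrix plus per-cell spatial coordinates and optional types.

    Attributes
    ----------
    X : ndarray of shape (n_cells, n_genes)
        Non-negative expression values.
    coords : ndarray of shape (n_cells, 2)
        2-D spatial positions, same length unit on both axes.
    cell_types : ndarray of str, optional
        One label per cell; required for heterogeneous-graph modelling.
    gene_names, cell_ids : sequences of unique strings.
    """

    X: np.ndarray
    coords: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    cell_types: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.cell_types is not None:
            self.cell_types = np.asarray(self.cell_types, dtype=object)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D (cells x genes)")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("X contains NaN or Inf")
        if self.coords.shape != (self.X.shape[0], 2):
            raise AlignmentError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.X.shape[0]} cells x 2"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates contain NaN or Inf")
        if len(self.gene_names) != self.X.shape[1]:
            raise AlignmentError("gene_names length != number of genes")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError("gene_names are not unique")
        if len(self.cell_ids) != self.X.shape[0]:
            raise AlignmentError("cell_ids length != number of cells")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids are not unique")
        if self.cell_types is not None:
            if len(self.cell_types) != self.X.shape[0]:
                raise AlignmentError("cell_types length != number of cells")
            if any(t is None or (isinstance(t, float) and np.isnan(t))
                   for t in self.cell_types):
                raise ValidationError("cell_types has missing values")

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_names == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in dataset")
        return int(idx[0])


@dataclass
class CellGraph:
    """Directed edge set over cells with 0-based node indices.

    Spatial-proximity graphs are stored with both orientations of every
    contact present (symmetric edge set); directionality enters later through
    the model, not the graph.
    """

    n_nodes: int
    edges: np.ndarray  # (E, 2) int array of ordered pairs
    self_loops_added: bool = False

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValidationError("edge index out of range")
            keys = self.edges[:, 0] * self.n_nodes + self.edges[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise ValidationError("duplicate ordered edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency matrix A (no self loops unless stored as edges)."""
        if self.edges.size == 0:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        data = np.ones(len(self.edges))
        return sp.csr_matrix(
            (data, (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_nodes, self.n_nodes),
        )

    def augmented_adjacency(self) -> sp.csr_matrix:
        """A-tilde = A + I (self loops added)."""
        return (self.adjacency() + sp.identity(self.n_nodes, format="csr")).tocsr()

    def degree_matrices(self, augmented: bool = True):
        """(D+, D-) diagonal out-/in-degree vectors of A (or A-tilde)."""
        A = self.augmented_adjacency() if augmented else self.adjacency()
        d_out = np.asarray(A.sum(axis=1)).ravel()
        d_in = np.asarray(A.sum(axis=0)).ravel()
        return d_out, d_in

    def undirected_contacts(self) -> np.ndarray:
        """Unique unordered pairs (i < j) present in the edge set."""
        if self.edges.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        lo = np.minimum(self.edges[:, 0], self.edges[:, 1])
        hi = np.maximum(self.edges[:, 0], self.edges[:, 1])
        pairs = np.unique(np.stack([lo, hi], axis=1), axis=0)
        return pairs[pairs[:, 0] != pairs[:, 1]]

    def edge_set(self) -> set:
        return set(map(tuple, self.edges))

    def is_symmetric(self) -> bool:
        es = self.edge_set()
        return all((j, i) in es for (i, j) in es)

    @classmethod
    def from_contacts(cls, n_nodes: int, contacts: np.ndarray) -> "CellGraph":
        """Build a symmetric graph from unordered contact pairs."""
        contacts = np.asarray(contacts, dtype=np.int64).reshape(-1, 2)
        if contacts.size == 0:
            return cls(n_nodes=n_nodes, edges=np.empty((0, 2), dtype=np.int64))
        both = np.vstack([contacts, contacts[:, ::-1]])
        both = np.unique(both, axis=0)
        return cls(n_nodes=n_nodes, edges=both)


@dataclass
class EdgeSplit:
    """Train/test partition of contacts with sampled test negatives.

    The split is made on undirected contacts so both orientations of a pair
    always land on the same side; edge lists store both orientations.
    """

    train_pos: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray
    test_fraction: float
    seed: int

    @property
    def n_train_contacts(self) -> int:
        return len(self.train_pos) // 2

    @property
    def n_test_contacts(self) -> int:
        return len(self.test_pos) // 2


# ---------------------------------------------------------------------------
# loading

def _read_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in {".csv"}:
        return pd.read_csv(path, index_col=0)
    if suffix in {".tsv", ".txt"}:
        return pd.read_csv(path, sep="\t", index_col=0)
    raise FormatError(f"unrecognised table format: {path}")


def load_dataset(
    expression_path,
    coords_path,
    types_path=None,
    *,
    gene_names_path=None,
    cell_ids_path=None,
) -> SpatialDataset:
    """Read expression + coordinates (+ optional cell types) into a dataset.

    Supported expression formats: CSV/TSV (cells x genes, first column is the
    cell id, header holds gene names), MatrixMarket ``.mtx`` (cells x genes,
    with `gene_names_path` and `cell_ids_path` plain-text sidecar lists), and
    ``.h5ad`` annotated matrices. Rows are aligned to the coordinate file by
    cell id when both carry ids, otherwise by row order.
    """
    expression_path = Path(expression_path)
    coords_path = Path(coords_path)
    suffix = expression_path.suffix.lower()

    if suffix == ".mtx":
        M = mmread(expression_path)
        X = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
        if gene_names_path is None or cell_ids_path is None:
            raise FormatError("MTX input needs gene_names_path and cell_ids_path")
        gene_names = np.loadtxt(gene_names_path, dtype=str, ndmin=1)
        cell_ids = np.loadtxt(cell_ids_path, dtype=str, ndmin=1)
        expr = pd.DataFrame(np.asarray(X), index=cell_ids, columns=gene_names)
    elif suffix == ".h5ad":
        import anndata  # optional dependency

        ad = anndata.read_h5ad(expression_path)
        M = ad.X.toarray() if sp.issparse(ad.X) else np.asarray(ad.X)
        expr = pd.DataFrame(M, index=ad.obs_names, columns=ad.var_names)
    elif suffix in {".csv", ".tsv", ".txt"}:
        expr = _read_table(expression_path)
    else:
        raise FormatError(f"unrecognised expression format: {expression_path}")

    coords = _read_table(coords_path)
    if coords.shape[1] < 2:
        raise ValidationError("coordinate file must have x and y columns")
    coords = coords.iloc[:, :2]

    if expr.shape[0] != coords.shape[0]:
        raise AlignmentError(
            f"expression has {expr.shape[0]} cells but coordinates "
            f"have {coords.shape[0]}"
        )
    expr_ids = expr.index.astype(str)
    coord_ids = coords.index.astype(str)
    if set(expr_ids) == set(coord_ids):
        coords = coords.loc[expr_ids]
    # else: positional alignment, row counts already checked

    cell_types = None
    if types_path is not None:
        types = _read_table(Path(types_path))
        if types.shape[0] != expr.shape[0]:
            raise AlignmentError("cell type file row count mismatch")
        if set(types.index.astype(str)) == set(expr_ids):
            types = types.loc[expr_ids]
        cell_types = types.iloc[:, 0].astype(str).to_numpy()

    return SpatialDataset(
        X=expr.to_numpy(dtype=float),
        coords=coords.to_numpy(dtype=float),
        gene_names=expr.columns.astype(str).to_numpy(),
        cell_ids=expr_ids.to_numpy(),
        cell_types=cell_types,
    )


# ---------------------------------------------------------------------------
# graph construction

def _knn_distances(coords: np.ndarray, k: int) -> np.ndarray:
    """Distance of every cell to its k-th nearest neighbour (self excluded)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    kq = min(k + 1, n)
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=kq)
    dist = np.atleast_2d(dist)
    return dist[:, -1]


def compute_distance_threshold(
    coords: np.ndarray, k: int = 3, percentile: float = 95.0
) -> float:
    """Direct-contact distance cutoff from the k-NN distance distribution.

    Returns the given percentile of each cell's k-th nearest-neighbour
    Euclidean distance. Cells further apart than this are considered not in
    physical contact regardless of neighbour rank.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise InsufficientDataError("need at least 2 cells for a threshold")
    return float(np.percentile(_knn_distances(coords, k), percentile))


def build_adjacency(coords: np.ndarray, threshold: float, k: int = 3) -> CellGraph:
    """Direct-contact graph: k nearest neighbours within the cutoff, union-symmetrised.

    Each cell nominates its ``k`` nearest neighbours whose distance is at most
    ``threshold``; any pair nominated by either member becomes a contact and
    both orientations are emitted. Ties in distance are broken by lower cell
    index for determinism. No self loops are added here.
    """
    coords = np.asarray(coords, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(coords)
    if n < 2:
        return CellGraph(n_nodes=n, edges=np.empty((0, 2), dtype=np.int64))

    kq = min(k + 1, n)
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=kq)
    dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)

    contacts = set()
    for i in range(n):
        cand = [(dist[i, c], idx[i, c]) for c in range(kq) if idx[i, c] != i]
        cand.sort(key=lambda t: (t[0], t[1]))  # deterministic tie-break
        for d, j in cand[:k]:
            if d <= threshold:
                contacts.add((min(i, j), max(i, j)))
    if not contacts:
        return CellGraph(n_nodes=n, edges=np.empty((0, 2), dtype=np.int64))
    return CellGraph.from_contacts(n, np.array(sorted(contacts)))


def split_edges(
    graph: CellGraph, test_fraction: float = 0.1, seed: int = 0
) -> EdgeSplit:
    """Hold out a fraction of contacts for testing, with matched negatives.

    Contacts (undirected pairs) are partitioned at random; test negatives are
    ordered pairs of distinct cells that are not adjacent in the graph,
    sampled uniformly by rejection, matched in count to the test positives.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    contacts = graph.undirected_contacts()
    n_contacts = len(contacts)
    if n_contacts < 10:
        raise InsufficientDataError(
            f"graph has only {n_contacts} contacts; need >= 10 to split"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_contacts)
    n_test = int(round(test_fraction * n_contacts))
    n_test = max(1, min(n_test, n_contacts - 1))
    test_c = contacts[order[:n_test]]
    train_c = contacts[order[n_test:]]

    def both_dirs(pairs: np.ndarray) -> np.ndarray:
        return np.vstack([pairs, pairs[:, ::-1]])

    positive = graph.edge_set()
    n = graph.n_nodes
    n_neg = 2 * n_test
    neg = sample_negative_pairs(n, n_neg, positive, rng)
    return EdgeSplit(
        train_pos=both_dirs(train_c),
        test_pos=both_dirs(test_c),
        test_neg=neg,
        test_fraction=test_fraction,
        seed=seed,
    )


def sample_negative_pairs(
    n_nodes: int, count: int, forbidden: set, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly sample ordered pairs of distinct cells outside `forbidden`.

    Rejection sampling without replacement; raises if the graph is so dense
    that not enough non-edges exist.
    """
    capacity = n_nodes * (n_nodes - 1) - len(forbidden)
    if capacity < count:
        raise InsufficientDataError("not enough non-adjacent pairs to sample")
    chosen: set = set()
    out = []
    # draw in batches; rejection on self pairs, positives and duplicates
    while len(out) < count:
        m = max(32, 2 * (count - len(out)))
        src = rng.integers(0, n_nodes, size=m)
        dst = rng.integers(0, n_nodes, size=m)
        for i, j in zip(src, dst):
            pair = (int(i), int(j))
            if i == j or pair in forbidden or pair in chosen:
                continue
            chosen.add(pair)
            out.append(pair)
            if len(out) == count:
                break
    return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# i/o helpers

def write_edges_tsv(path, graph_or_edges, cell_ids: Optional[Sequence] = None) -> None:
    """Write an edge list as 2-column TSV (source_id, target_id)."""
    edges = getattr(graph_or_edges, "edges", graph_or_edges)
    edges = np.asarray(edges).reshape(-1, 2)
    if cell_ids is not None:
        cell_ids = np.asarray(cell_ids)
        rows = pd.DataFrame(
            {"source_id": cell_ids[edges[:, 0]], "target_id": cell_ids[edges[:, 1]]}
        )
    else:
        rows = pd.DataFrame({"source_id": edges[:, 0], "target_id": edges[:, 1]})
    rows.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path, cell_ids: Optional[Sequence] = None) -> np.ndarray:
    """Read a 2-column TSV edge list back into an (E, 2) index array."""
    df = pd.read_csv(path, sep="\t")
    if cell_ids is not None:
        lut = {str(c): i for i, c in enumerate(cell_ids)}
        return np.array(
            [[lut[str(s)], lut[str(t)]] for s, t in zip(df.iloc[:, 0], df.iloc[:, 1])],
            dtype=np.int64,
        ).reshape(-1, 2)
    return df.iloc[:, :2].to_numpy(dtype=np.int64)
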