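"""Spatial graph construction: loading, thresholds, k-NN contacts, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ccinet.graph import (
    AlignmentError,
    CellGraph,
    FormatError,
    InsufficientDataError,
    ValidationError,
    build_adjacency,
    compute_distance_threshold,
    load_dataset,
    split_edges,
)


def _write_csv_inputs(tmp_path, X, coords, ids=None, genes=None):
    n, m = X.shape
    ids = ids or [f"c{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(m)]
    ep = tmp_path / "expr.csv"
    cp = tmp_path / "coords.csv"
    pd.DataFrame(X, index=ids, columns=genes).to_csv(ep)
    pd.DataFrame(coords, index=ids, columns=["x", "y"]).to_csv(cp)
    return ep, cp


class TestLoading:
    def test_csv_roundtrip(self, tmp_path):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        coords = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        ep, cp = _write_csv_inputs(tmp_path, X, coords)
        ds = load_dataset(ep, cp)
        assert ds.n_cells == 3 and ds.n_genes == 2
        np.testing.assert_allclose(ds.X, X)

    def test_row_count_mismatch_raises(self, tmp_path):
        ep, _ = _write_csv_inputs(tmp_path, np.ones((3, 2)), np.zeros((3, 2)))
        cp = tmp_path / "coords4.csv"
        pd.DataFrame(np.zeros((4, 2)), index=[f"c{i}" for i in range(4)],
                     columns=["x", "y"]).to_csv(cp)
        with pytest.raises(AlignmentError):
            load_dataset(ep, cp)

    def test_nan_coords_rejected(self, tmp_path):
        coords = np.array([[0.0, 0.0], [np.nan, 1.0], [1.0, 1.0]])
        ep, cp = _write_csv_inputs(tmp_path, np.ones((3, 2)), coords)
        with pytest.raises(ValidationError):
            load_dataset(ep, cp)

    def test_unknown_extension_raises(self, tmp_path):
        p = tmp_path / "expr.xyz"
        p.write_text("nope")
        with pytest.raises(FormatError):
            load_dataset(p, p)

    def test_mtx_equals_csv(self, tmp_path):
        from scipy.io import mmwrite
        import scipy.sparse as sp

        rng = np.random.default_rng(0)
        X = np.round(rng.random((5, 4)) * 10, 3)
        coords = rng.random((5, 2))
        ep, cp = _write_csv_inputs(tmp_path, X, coords)
        mp = tmp_path / "expr.mtx"
        mmwrite(str(mp), sp.csr_matrix(X))
        gp = tmp_path / "genes.txt"
        ip = tmp_path / "cells.txt"
        gp.write_text("\n".join(f"g{j}" for j in range(4)) + "\n")
        ip.write_text("\n".join(f"c{i}" for i in range(5)) + "\n")
        ds_csv = load_dataset(ep, cp)
        ds_mtx = load_dataset(mp, cp, gene_names_path=gp, cell_ids_path=ip)
        np.testing.assert_allclose(ds_mtx.X, ds_csv.X)
        assert list(ds_mtx.gene_names) == list(ds_csv.gene_names)


class TestThreshold:
    def test_collinear_unit_spacing(self):
        coords = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        assert compute_distance_threshold(coords, k=1, percentile=95) == 1.0

    def test_percentile_at_least_median(self, random_coords):
        thr = compute_distance_threshold(random_coords, k=3, percentile=95)
        med = compute_distance_threshold(random_coords, k=3, percentile=50)
        assert thr >= med > 0

    def test_grid_matches_bruteforce_sort(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        coords = np.stack([xs.ravel(), ys.ravel()], axis=1)
        # brute force: full pairwise distances, per-cell 3rd smallest
        D = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        np.fill_diagonal(D, np.inf)
        knn3 = np.sort(D, axis=1)[:, 2]
        for pct in (50, 75, 95):
            expected = float(np.percentile(knn3, pct))
            got = compute_distance_threshold(coords, k=3, percentile=pct)
            assert got == pytest.approx(expected)

    def test_single_point_insufficient(self):
        with pytest.raises(InsufficientDataError):
            compute_distance_threshold(np.zeros((1, 2)))


def _bruteforce_adjacency(coords, threshold, k):
    """O(N^2) reference: per-cell k nearest within threshold, union-symmetric."""
    n = len(coords)
    D = np.linalg.norm(coords[:, None] - coords[None], axis=2)
    contacts = set()
    for i in range(n):
        order = sorted((D[i, j], j) for j in range(n) if j != i)
        for d, j in order[:k]:
            if d <= threshold:
                contacts.add((min(i, j), max(i, j)))
    return contacts


class TestBuildAdjacency:
    def test_collinear_chain(self):
        coords = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        g = build_adjacency(coords, threshold=1.5, k=3)
        assert g.edge_set() == {(0, 1), (1, 0), (1, 2), (2, 1), (2, 3), (3, 2)}

    def test_single_cell_empty(self):
        g = build_adjacency(np.zeros((1, 2)), threshold=1.0)
        assert g.n_edges == 0

    def test_far_cells_no_edges(self):
        g = build_adjacency(np.array([[0.0, 0.0], [10.0, 0.0]]), threshold=1.0)
        assert g.n_edges == 0

    def test_symmetry_and_degree_bound(self, random_coords):
        thr = compute_distance_threshold(random_coords)
        g = build_adjacency(random_coords, thr, k=3)
        assert g.is_symmetric()
        # each node's own selections are at most k; out-degree in the
        # symmetric edge set can exceed k only through others selecting it
        A = g.adjacency().toarray()
        D = np.linalg.norm(random_coords[:, None] - random_coords[None], axis=2)
        np.fill_diagonal(D, np.inf)
        for i in range(len(random_coords)):
            own = sum(1 for j in np.argsort(D[i])[:3] if D[i, j] <= thr)
            assert A[i].sum() >= own

    def test_threshold_monotonicity(self, random_coords):
        counts = [build_adjacency(random_coords, t, k=3).n_edges
                  for t in (1.0, 3.0, 8.0, 100.0)]
        assert counts == sorted(counts)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(2, 50), seed=st.integers(0, 10_000),
           k=st.integers(1, 4))
    def test_matches_bruteforce_reference(self, n, seed, k):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10, size=(n, 2))
        thr = float(rng.uniform(0.5, 5.0))
        g = build_adjacency(coords, thr, k=k)
        got = {tuple(p) for p in g.undirected_contacts()}
        assert got == _bruteforce_adjacency(coords, thr, k)


class TestSplit:
    def _graph_100_contacts(self):
        # ring of 100 nodes: exactly 100 undirected contacts
        n = 100
        contacts = np.array([(i, (i + 1) % n) for i in range(n)])
        contacts = np.array([(min(a, b), max(a, b)) for a, b in contacts])
        return CellGraph.from_contacts(n, contacts)

    def test_ninety_ten_counts(self):
        g = self._graph_100_contacts()
        split = split_edges(g, test_fraction=0.1, seed=0)
        assert split.n_train_contacts == 90
        assert split.n_test_contacts == 10
        assert len(split.test_neg) == len(split.test_pos) == 20

    def test_partition_is_exact(self):
        g = self._graph_100_contacts()
        split = split_edges(g, test_fraction=0.1, seed=3)
        train = set(map(tuple, split.train_pos))
        test = set(map(tuple, split.test_pos))
        assert train & test == set()
        assert train | test == g.edge_set()

    def test_negatives_disjoint_from_positives_exhaustive(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 10, size=(30, 2))
        g = build_adjacency(coords, compute_distance_threshold(coords), k=3)
        split = split_edges(g, test_fraction=0.2, seed=7)
        positives = g.edge_set()
        for i, j in split.test_neg:
            assert (i, j) not in positives
            assert i != j

    def test_deterministic_given_seed(self):
        g = self._graph_100_contacts()
        s1 = split_edges(g, 0.1, seed=9)
        s2 = split_edges(g, 0.1, seed=9)
        np.testing.assert_array_equal(s1.train_pos, s2.train_pos)
        np.testing.assert_array_equal(s1.test_neg, s2.test_neg)

    def test_bad_fraction_and_small_graph(self):
        g = self._graph_100_contacts()
        with pytest.raises(ValueError):
            split_edges(g, test_fraction=1.5, seed=0)
        tiny = CellGraph.from_contacts(4, np.array([[0, 1], [1, 2]]))
        with pytest.raises(InsufficientDataError):
            split_edges(tiny, 0.1, seed=0)


def test_cellgraph_invariants():
    with pytest.raises(ValidationError):
        CellGraph(n_nodes=3, edges=np.array([[0, 5]]))
    with pytest.raises(ValidationError):
        CellGraph(n_nodes=3, edges=np.array([[0, 1], [0, 1]]))
    g = CellGraph.from_contacts(3, np.array([[0, 1]]))
    d_out, d_in = g.degree_matrices(augmented=True)
    # A~ = A + I: recount degrees directly
    A = g.augmented_adjacency().toarray()
    np.testing.assert_array_equal(d_out, A.sum(axis=1))
    np.testing.assert_array_equal(d_in, A.sum(axis=0))
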