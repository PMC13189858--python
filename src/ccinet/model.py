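"""Directed graph autoencoder for cell-cell interaction reconstruction.

Every cell carries two latent embeddings: a sender code (rows of ``Z_S``) and
a receiver code (rows of ``Z_T``), learned by a two-layer directed graph
convolution encoder and combined by an asymmetric inner-product decoder,

    A'[i, j] = sigmoid(<Z_S[i], Z_T[j]>),

so that A' need not be symmetric even though the spatial training graph is.
Message passing uses the degree-normalised adjacency

    A_hat = (D+)^-beta  A_tilde  (D-)^-alpha,

with A_tilde = A + I by default and out-/in-degree diagonal matrices D+, D-.
The encoder reads

    Z_S = A_hat   ReLU(A_hat^T S0 W_S0) W_T1,
    Z_T = A_hat^T ReLU(A_hat   T0 W_T0) W_S1,

with S0 = T0 = X unless a ligand/receptor initialisation supplies distinct
inputs. In heterogeneous mode each weight matrix is replaced by a per-cell-
type stack, applied row-wise according to each node's type before
aggregation. The model is small enough that training runs on plain numpy
with hand-written gradients and an Adam optimiser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .graph import CellGraph, EdgeSplit, SpatialDataset, sample_negative_pairs

_CLIP = 1e-7


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class NormalizedAdjacency:
    """Degree-normalised directed adjacency A_hat = (D+)^-beta A~ (D-)^-alpha."""

    matrix: sp.csr_matrix
    alpha: float
    beta: float
    self_loops_added: bool

    @property
    def T(self) -> sp.csr_matrix:
        return self.matrix.T.tocsr()

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def normalize_adjacency(
    graph: CellGraph, alpha: float = 0.5, beta: float = 0.5,
    add_self_loops: bool = True,
) -> NormalizedAdjacency:
    """Build A_hat from a cell graph.

    Self loops are added before degree computation by default (A~ = A + I).
    A zero out-/in-degree contributes a scaling factor of 1 rather than a
    division by zero, so isolated cells stay finite.
    """
    A = graph.augmented_adjacency() if add_self_loops else graph.adjacency()
    if A.size and A.min() < 0:
        raise ValueError("adjacency has negative entries")
    d_out = np.asarray(A.sum(axis=1)).ravel()
    d_in = np.asarray(A.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        s_out = np.where(d_out > 0, d_out ** (-beta), 1.0)
        s_in = np.where(d_in > 0, d_in ** (-alpha), 1.0)
    Ahat = sp.diags(s_out) @ A @ sp.diags(s_in)
    return NormalizedAdjacency(
        matrix=Ahat.tocsr(), alpha=alpha, beta=beta, self_loops_added=add_self_loops
    )


# ---------------------------------------------------------------------------
# layers

def _rowwise(M: np.ndarray, W_stack: np.ndarray, types: np.ndarray) -> np.ndarray:
    """Apply W_stack[type(j)] to row j of M. W_stack has shape (K, din, dout)."""
    K = W_stack.shape[0]
    if K == 1:
        return M @ W_stack[0]
    out = np.empty((M.shape[0], W_stack.shape[2]))
    for k in range(K):
        mask = types == k
        if mask.any():
            out[mask] = M[mask] @ W_stack[k]
    return out


def _rowwise_backward(
    M: np.ndarray, W_stack: np.ndarray, types: np.ndarray, grad_out: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Gradients of rowwise application: (dM, dW_stack)."""
    K = W_stack.shape[0]
    dW = np.zeros_like(W_stack)
    if K == 1:
        dW[0] = M.T @ grad_out
        return grad_out @ W_stack[0].T, dW
    dM = np.empty_like(M)
    for k in range(K):
        mask = types == k
        if mask.any():
            dW[k] = M[mask].T @ grad_out[mask]
            dM[mask] = grad_out[mask] @ W_stack[k].T
        # rows of absent types never occur; dM left unwritten only for them
    return dM, dW


def directed_layer(Ahat, S, T, W_S, W_T, activation=None):
    """One homogeneous directed convolution: simultaneous S/T update.

    ``S_next = act(A_hat (T W_T))`` aggregates receiver embeddings of
    out-neighbours; ``T_next = act(A_hat^T (S W_S))`` aggregates sender
    embeddings of in-neighbours. Both are computed from the input S, T.
    """
    A = Ahat.matrix if isinstance(Ahat, NormalizedAdjacency) else Ahat
    act = activation if activation is not None else (lambda x: x)
    S_next = act(A @ (T @ W_T))
    T_next = act(A.T @ (S @ W_S))
    return S_next, T_next


def hetero_directed_layer(Ahat, S, T, cell_types, W_S_stack, W_T_stack,
                          activation=None):
    """Type-aware directed convolution.

    Row j of the message matrix is first transformed by its own type's weight
    matrix (``T[j] @ W_T[type(j)]``), then aggregated through A_hat exactly as
    in the homogeneous layer; symmetric for the T update via A_hat^T and W_S.
    """
    A = Ahat.matrix if isinstance(Ahat, NormalizedAdjacency) else Ahat
    types = np.asarray(cell_types)
    W_S_stack = np.asarray(W_S_stack)
    W_T_stack = np.asarray(W_T_stack)
    K = W_S_stack.shape[0]
    if types.max(initial=-1) >= K:
        raise KeyError("cell type without registered weights")
    act = activation if activation is not None else (lambda x: x)
    S_next = act(A @ _rowwise(T, W_T_stack, types))
    T_next = act(A.T @ _rowwise(S, W_S_stack, types))
    return S_next, T_next


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# model

@dataclass
class ReconstructionResult:
    """Dense edge-probability matrix with a thresholded edge list."""

    A_prime: np.ndarray
    threshold: float
    predicted_edges: np.ndarray
    metrics: Optional[dict] = None


@dataclass
class DigaeModel:
    """Trained (or initialised) directed graph autoencoder.

    Holds the weight stacks (leading axis = cell type; length 1 in
    homogeneous mode), the normalised adjacency used for message passing,
    cached latent codes, and the training trace.
    """

    mode: str
    weights: Dict[str, np.ndarray]
    Ahat: NormalizedAdjacency
    type_codes: np.ndarray
    Z_S: Optional[np.ndarray] = None
    Z_T: Optional[np.ndarray] = None
    loss_trace: list = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0
    scaler: Optional[Dict[str, np.ndarray]] = None

    @property
    def n_cells(self) -> int:
        return self.Ahat.matrix.shape[0]

    def encode(self, S0: np.ndarray, T0: Optional[np.ndarray] = None):
        """Forward pass with the stored weights (and train-time feature scaling)."""
        T0 = S0 if T0 is None else T0
        exp_S = self.weights["W_S0"].shape[1]
        exp_T = self.weights["W_T0"].shape[1]
        if S0.shape[1] != exp_S or T0.shape[1] != exp_T:
            raise ValueError(
                f"model expects S0 width {exp_S} and T0 width {exp_T} "
                f"(got {S0.shape[1]}, {T0.shape[1]}); a ligand/receptor-"
                "initialised model must be re-encoded with the same panels"
            )
        if self.scaler is not None:
            S0 = (S0 - self.scaler["mean_S"]) / self.scaler["std_S"]
            T0 = (T0 - self.scaler["mean_T"]) / self.scaler["std_T"]
        Z_S, Z_T, _ = _forward(self.Ahat, S0, T0, self.weights, self.type_codes)
        return Z_S, Z_T

    def score_pairs(self, pairs: np.ndarray,
                    Z: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> np.ndarray:
        """Edge probabilities sigmoid(<Z_S[i], Z_T[j]>) for ordered pairs."""
        Z_S, Z_T = (self.Z_S, self.Z_T) if Z is None else Z
        pairs = np.asarray(pairs).reshape(-1, 2)
        logits = np.einsum("ed,ed->e", Z_S[pairs[:, 0]], Z_T[pairs[:, 1]])
        return _sigmoid(logits)

    def save(self, path) -> None:
        meta = {
            "mode": self.mode,
            "alpha": self.Ahat.alpha,
            "beta": self.Ahat.beta,
            "self_loops": self.Ahat.self_loops_added,
            "seed": self.seed,
            "hyperparams": self.hyperparams,
        }
        arrays = {f"weight_{k}": v for k, v in self.weights.items()}
        if self.scaler is not None:
            arrays.update({f"scaler_{k}": v for k, v in self.scaler.items()})
        Acoo = self.Ahat.matrix.tocoo()
        np.savez_compressed(
            path,
            Z_S=self.Z_S, Z_T=self.Z_T,
            type_codes=self.type_codes,
            loss_trace=np.asarray(self.loss_trace),
            Ahat_row=Acoo.row, Ahat_col=Acoo.col, Ahat_data=Acoo.data,
            Ahat_shape=np.asarray(Acoo.shape),
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "DigaeModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            weights = {k[len("weight_"):]: z[k] for k in z.files
                       if k.startswith("weight_")}
            scaler = {k[len("scaler_"):]: z[k] for k in z.files
                      if k.startswith("scaler_")} or None
            shape = tuple(z["Ahat_shape"])
            Ahat = NormalizedAdjacency(
                matrix=sp.csr_matrix(
                    (z["Ahat_data"], (z["Ahat_row"], z["Ahat_col"])), shape=shape
                ),
                alpha=meta["alpha"], beta=meta["beta"],
                self_loops_added=meta["self_loops"],
            )
            return cls(
                mode=meta["mode"], weights=weights, Ahat=Ahat,
                type_codes=z["type_codes"],
                Z_S=z["Z_S"], Z_T=z["Z_T"],
                loss_trace=list(z["loss_trace"]),
                hyperparams=meta["hyperparams"], seed=meta["seed"],
                scaler=scaler,
            )


def decode(Z_S: np.ndarray, Z_T: np.ndarray, threshold: float = 0.5
           ) -> ReconstructionResult:
    """Asymmetric inner-product decoder: A' = sigmoid(Z_S Z_T^T).

    No symmetrisation is applied; A'[i,j] and A'[j,i] are independent scores.
    The predicted edge list keeps off-diagonal pairs with A' >= threshold
    (inclusive boundary).
    """
    Z_S = np.atleast_2d(Z_S)
    Z_T = np.atleast_2d(Z_T)
    if Z_S.shape[1] != Z_T.shape[1]:
        raise ValueError("latent dimensions of Z_S and Z_T differ")
    A_prime = _sigmoid(Z_S @ Z_T.T)
    edges = _threshold_edges(A_prime, threshold)
    return ReconstructionResult(A_prime=A_prime, threshold=threshold,
                                predicted_edges=edges)


def _threshold_edges(A_prime: np.ndarray, threshold: float) -> np.ndarray:
    mask = A_prime >= threshold
    if A_prime.shape[0] == A_prime.shape[1]:
        np.fill_diagonal(mask, False)
    src, dst = np.nonzero(mask)
    return np.stack([src, dst], axis=1).astype(np.int64)


def reconstruction_loss(A_prime: np.ndarray, train_pos: np.ndarray,
                        train_neg: np.ndarray) -> float:
    """Mean binary cross-entropy over positive and negative pairs.

    Probabilities are clipped to [1e-7, 1 - 1e-7] for numerical safety.
    """
    train_pos = np.asarray(train_pos).reshape(-1, 2)
    train_neg = np.asarray(train_neg).reshape(-1, 2)
    if len(train_pos) == 0:
        raise ValueError("empty positive edge set")
    p_pos = np.clip(A_prime[train_pos[:, 0], train_pos[:, 1]], _CLIP, 1 - _CLIP)
    p_neg = np.clip(A_prime[train_neg[:, 0], train_neg[:, 1]], _CLIP, 1 - _CLIP)
    losses = np.concatenate([-np.log(p_pos), -np.log1p(-p_neg)])
    return float(losses.mean())


# ---------------------------------------------------------------------------
# forward / backward

def _forward(Ahat: NormalizedAdjacency, S0, T0, weights, types):
    """Two-layer encoder forward pass; returns (Z_S, Z_T, cache)."""
    A, At = Ahat.matrix, Ahat.T
    P_S = _rowwise(S0, weights["W_S0"], types)
    pre_S = At @ P_S
    H_S = _relu(pre_S)
    Q_S = _rowwise(H_S, weights["W_T1"], types)
    Z_S = A @ Q_S

    P_T = _rowwise(T0, weights["W_T0"], types)
    pre_T = A @ P_T
    H_T = _relu(pre_T)
    Q_T = _rowwise(H_T, weights["W_S1"], types)
    Z_T = At @ Q_T
    cache = dict(S0=S0, T0=T0, pre_S=pre_S, H_S=H_S, pre_T=pre_T, H_T=H_T)
    return Z_S, Z_T, cache


def _backward(Ahat, weights, types, cache, Z_S, Z_T, dZ_S, dZ_T):
    """Gradients of the loss w.r.t. every weight stack."""
    A, At = Ahat.matrix, Ahat.T
    grads = {}
    # sender branch: Z_S = A @ rowwise(H_S, W_T1); H_S = relu(At @ rowwise(S0, W_S0))
    dQ_S = At @ dZ_S
    dH_S, grads["W_T1"] = _rowwise_backward(cache["H_S"], weights["W_T1"], types, dQ_S)
    dpre_S = dH_S * (cache["pre_S"] > 0)
    dP_S = A @ dpre_S
    _, grads["W_S0"] = _rowwise_backward(cache["S0"], weights["W_S0"], types, dP_S)
    # receiver branch: Z_T = At @ rowwise(H_T, W_S1); H_T = relu(A @ rowwise(T0, W_T0))
    dQ_T = A @ dZ_T
    dH_T, grads["W_S1"] = _rowwise_backward(cache["H_T"], weights["W_S1"], types, dQ_T)
    dpre_T = dH_T * (cache["pre_T"] > 0)
    dP_T = At @ dpre_T
    _, grads["W_T0"] = _rowwise_backward(cache["T0"], weights["W_T0"], types, dP_T)
    return grads


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[-2] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


def _init_weights(rng, K, din_S, din_T, hidden, latent):
    return {
        "W_S0": _glorot(rng, (K, din_S, hidden)),
        "W_T0": _glorot(rng, (K, din_T, hidden)),
        "W_S1": _glorot(rng, (K, hidden, latent)),
        "W_T1": _glorot(rng, (K, hidden, latent)),
    }


class _Adam:
    def __init__(self, params, lr=0.01, b1=0.9, b2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k] + self.weight_decay * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _encode_types(dataset_types, mode: str, n: int):
    """Map string labels to contiguous int codes; all-zero in homogeneous mode."""
    if mode == "homogeneous" or dataset_types is None:
        return np.zeros(n, dtype=np.int64), 1
    labels = np.asarray(dataset_types)
    uniq = np.unique(labels)
    lut = {t: i for i, t in enumerate(uniq)}
    return np.array([lut[t] for t in labels], dtype=np.int64), len(uniq)


def train(
    dataset: SpatialDataset,
    split: EdgeSplit,
    mode: str = "homogeneous",
    *,
    hidden: int = 64,
    latent: int = 32,
    epochs: int = 200,
    lr: float = 0.01,
    weight_decay: float = 0.01,
    alpha: float = 0.5,
    beta: float = 0.5,
    add_self_loops: bool = True,
    S0: Optional[np.ndarray] = None,
    T0: Optional[np.ndarray] = None,
    standardize: bool = True,
    seed: int = 0,
) -> DigaeModel:
    """Fit the autoencoder by minimising edge BCE with Adam.

    Message passing uses only the training edges (held-out test edges are
    masked from the adjacency to avoid leakage). Negatives for the loss are
    resampled fresh every epoch from non-adjacent ordered pairs, matched in
    count to the training positives. Deterministic given ``seed``.

    ``S0``/``T0`` override the default initialisation S0 = T0 = X, e.g. with
    ligand-only and receptor-only expression submatrices; the first-layer
    weight shapes follow each side's own width.

    ``standardize`` z-scores each input feature before encoding (the scaler
    is stored on the model and re-applied by :meth:`DigaeModel.encode`);
    without it the raw expression scale saturates the decoder early in
    training.
    """
    if mode not in ("homogeneous", "heterogeneous"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "heterogeneous" and dataset.cell_types is None:
        raise ValueError("heterogeneous mode requires cell_types")
    n = dataset.n_cells
    S0 = dataset.X if S0 is None else np.asarray(S0, dtype=float)
    T0 = dataset.X if T0 is None else np.asarray(T0, dtype=float)
    if S0.shape[0] != n or T0.shape[0] != n:
        raise ValueError("S0/T0 row count must equal the number of cells")

    scaler = None
    if standardize:
        scaler = {
            "mean_S": S0.mean(axis=0), "std_S": np.maximum(S0.std(axis=0), 1e-8),
            "mean_T": T0.mean(axis=0), "std_T": np.maximum(T0.std(axis=0), 1e-8),
        }
        S0 = (S0 - scaler["mean_S"]) / scaler["std_S"]
        T0 = (T0 - scaler["mean_T"]) / scaler["std_T"]

    train_graph = CellGraph(n_nodes=n, edges=np.asarray(split.train_pos))
    Ahat = normalize_adjacency(train_graph, alpha=alpha, beta=beta,
                               add_self_loops=add_self_loops)
    types, K = _encode_types(dataset.cell_types, mode, n)

    rng = np.random.default_rng(seed)
    weights = _init_weights(rng, K, S0.shape[1], T0.shape[1], hidden, latent)
    opt = _Adam(weights, lr=lr, weight_decay=weight_decay)

    pos = np.asarray(split.train_pos).reshape(-1, 2)
    # negatives may not collide with any known positive edge (train or test)
    forbidden = set(map(tuple, pos)) | set(map(tuple,
                                               np.asarray(split.test_pos).reshape(-1, 2)))
    n_pairs = len(pos)
    trace = []
    Z_S = Z_T = None
    for epoch in range(epochs):
        neg = sample_negative_pairs(n, n_pairs, forbidden, rng)
        Z_S, Z_T, cache = _forward(Ahat, S0, T0, weights, types)
        logits = np.concatenate([
            np.einsum("ed,ed->e", Z_S[pos[:, 0]], Z_T[pos[:, 1]]),
            np.einsum("ed,ed->e", Z_S[neg[:, 0]], Z_T[neg[:, 1]]),
        ])
        y = np.concatenate([np.ones(n_pairs), np.zeros(n_pairs)])
        p = _sigmoid(logits)
        pc = np.clip(p, _CLIP, 1 - _CLIP)
        loss = float(-(y * np.log(pc) + (1 - y) * np.log1p(-pc)).mean())
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        trace.append(loss)

        g = (p - y) / len(y)
        dZ_S = np.zeros_like(Z_S)
        dZ_T = np.zeros_like(Z_T)
        allp = np.vstack([pos, neg])
        np.add.at(dZ_S, allp[:, 0], g[:, None] * Z_T[allp[:, 1]])
        np.add.at(dZ_T, allp[:, 1], g[:, None] * Z_S[allp[:, 0]])
        grads = _backward(Ahat, weights, types, cache, Z_S, Z_T, dZ_S, dZ_T)
        opt.step(weights, grads)

    Z_S, Z_T, _ = _forward(Ahat, S0, T0, weights, types)
    return DigaeModel(
        mode=mode, weights=weights, Ahat=Ahat, type_codes=types,
        Z_S=Z_S, Z_T=Z_T, loss_trace=trace,
        hyperparams=dict(hidden=hidden, latent=latent, epochs=epochs, lr=lr,
                         weight_decay=weight_decay, alpha=alpha, beta=beta,
                         add_self_loops=add_self_loops, standardize=standardize),
        seed=seed,
        scaler=scaler,
    )


_DENSE_LIMIT = 20_000


def predict_interactions(model: DigaeModel, threshold: float = 0.5
                         ) -> ReconstructionResult:
    """Materialise A' and the thresholded directed edge list (self pairs excluded).

    For very large tissues (N > 20 000) the dense matrix is not built; use
    ``model.score_pairs`` on candidate pairs instead.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if model.Z_S is None:
        raise ValueError("model has no cached latent codes; train or encode first")
    if model.n_cells > _DENSE_LIMIT:
        raise MemoryError(
            f"dense A' disabled for N > {_DENSE_LIMIT}; score candidate pairs "
            "with model.score_pairs instead"
        )
    return decode(model.Z_S, model.Z_T, threshold=threshold)
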