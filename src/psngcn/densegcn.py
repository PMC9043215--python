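"""Densely connected graph convolutional classifier over the patient network.

A graph convolution block computes sigma(A_norm @ H @ W) with A_norm the
symmetrically normalized adjacency (self-loops added). In the dense variant
every block's input is the concatenation of the raw node features and all
previous blocks' outputs, so information and gradients reach deep layers
directly — which is what lets the network stay trainable at ten layers on a
few hundred samples. The final classifier is an affine map plus softmax over
two classes on the last concatenated representation.

Training is transductive: the forward pass covers every node, the
cross-entropy loss is masked to training nodes, and model selection keeps the
parameters with the best validation accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np

from psngcn._nn import Adam, glorot_uniform, relu, softmax

logger = logging.getLogger(__name__)


@dataclass
class GCNConfig:
    """DenseGCN hyperparameters: 10 blocks of growth 32, lr 0.01, 500 epochs."""

    n_layers: int = 10
    hidden_dim: int = 32
    learning_rate: float = 0.01
    epochs: int = 500
    seed: int = 0
    dropout: float = 0.2
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_dim < 1 or self.epochs < 1:
            raise ValueError("n_layers, hidden_dim and epochs must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class GraphDataset:
    """Adjacency + node features + labels + split masks over one sample order."""

    adjacency: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    masks: Any  # SplitMasks (train/val/test index arrays)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if self.features.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("features/labels row count must match adjacency")


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    A_hat = A + np.eye(n)
    deg = A_hat.sum(axis=1)
    assert (deg > 0).all()  # self-loops guarantee positive degree
    inv_sqrt = 1.0 / np.sqrt(deg)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def gcn_layer(H: np.ndarray, A_norm: np.ndarray, W: np.ndarray,
              b: np.ndarray | float = 0.0, activation=relu) -> np.ndarray:
    """One graph convolution: activation(A_norm @ H @ W + b)."""
    H = np.asarray(H)
    if A_norm.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError("shape mismatch in graph convolution")
    return activation(A_norm @ H @ W + b)


def init_params(in_dim: int, cfg: GCNConfig, rng: np.random.Generator,
                n_classes: int = 2) -> dict[str, np.ndarray]:
    """Glorot-initialized weights for all dense blocks plus the classifier."""
    dtype = np.dtype(cfg.dtype)
    g = cfg.hidden_dim
    params: dict[str, np.ndarray] = {}
    for ell in range(cfg.n_layers):
        width_in = in_dim + ell * g
        params[f"W{ell}"] = glorot_uniform(rng, width_in, g, dtype)
        params[f"b{ell}"] = np.zeros(g, dtype=dtype)
    final = in_dim + cfg.n_layers * g
    params["Wc"] = glorot_uniform(rng, final, n_classes, dtype)
    params["bc"] = np.zeros(n_classes, dtype=dtype)
    return params


def densegcn_forward(
    X: np.ndarray,
    A_norm: np.ndarray,
    params: dict[str, np.ndarray],
    n_layers: int,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    _cache: dict | None = None,
    _agg0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense forward pass: returns (concatenated embedding, class probabilities).

    Block ell consumes [X, h_1, ..., h_{ell-1}] and emits
    h_ell = relu(A_norm @ input @ W_ell + b_ell). Because
    A_norm @ [X, h_1, ...] = [A_norm @ X, A_norm @ h_1, ...], each aggregated
    component is computed once into a shared buffer and reused, as a view, by
    every later block. During training (``dropout`` > 0, requires ``rng``)
    inverted dropout is applied per component — to X and to each block output
    — before aggregation, so a component is dropped consistently for all its
    consumers. ``_agg0`` optionally supplies a precomputed A_norm @ X for the
    dropout-free path (X never changes across evaluation calls).
    """
    dtype = params["W0"].dtype
    X = np.asarray(X, dtype=dtype)
    if dropout > 0.0 and rng is None:
        raise ValueError("dropout requires an rng")
    A_norm = np.asarray(A_norm, dtype=dtype)
    n, in_dim = X.shape
    growth = params["W0"].shape[1]
    train = dropout > 0.0

    def drop(a: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        if not train:
            return a, None
        mask = (rng.random(a.shape, dtype=np.float32) >= dropout).astype(dtype)
        mask /= dtype.type(1.0 - dropout)
        return a * mask, mask

    Xd, mask_x = drop(X)
    # Fortran order so each component's column block is contiguous for BLAS
    buf = np.empty((n, in_dim + n_layers * growth), dtype=dtype, order="F")
    if _agg0 is not None and not train:
        buf[:, :in_dim] = _agg0
    else:
        np.matmul(A_norm, Xd, out=buf[:, :in_dim])
    hds: list[np.ndarray] = []
    pres: list[np.ndarray] = []
    masks: list[np.ndarray | None] = []
    for ell in range(n_layers):
        w = in_dim + ell * growth
        pre = buf[:, :w] @ params[f"W{ell}"] + params[f"b{ell}"]
        hd, mask = drop(relu(pre))
        np.matmul(A_norm, hd, out=buf[:, w:w + growth])
        hds.append(hd)
        pres.append(pre)
        masks.append(mask)
    emb = np.hstack([Xd] + hds)
    logits = emb @ params["Wc"] + params["bc"]
    probs = softmax(logits.astype(np.float64))
    if _cache is not None:
        _cache.update(emb=emb, buf=buf, pres=pres, masks=masks,
                      in_dim=in_dim, growth=growth)
    return emb, probs


def _backward(
    cache: dict,
    A_norm: np.ndarray,
    params: dict[str, np.ndarray],
    n_layers: int,
    dlogits: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of the masked cross-entropy w.r.t. all parameters."""
    in_dim = cache["in_dim"]
    growth = cache["growth"]
    dtype = params["W0"].dtype
    emb = cache["emb"]
    buf = cache["buf"]
    dlogits = dlogits.astype(dtype)
    grads: dict[str, np.ndarray] = {
        "Wc": emb.T @ dlogits,
        "bc": dlogits.sum(axis=0),
    }
    demb = dlogits @ params["Wc"].T
    # gradient w.r.t. the aggregated buffer components (X slice unused)
    dbuf = np.zeros_like(buf)
    for ell in range(n_layers - 1, -1, -1):
        w = in_dim + ell * growth
        # dropped block output feeds the classifier and, via A_norm, buf
        dhd = demb[:, w:w + growth] + A_norm @ dbuf[:, w:w + growth]
        if cache["masks"][ell] is not None:
            dhd = dhd * cache["masks"][ell]
        dpre = dhd * (cache["pres"][ell] > 0)
        grads[f"W{ell}"] = buf[:, :w].T @ dpre
        grads[f"b{ell}"] = dpre.sum(axis=0)
        dbuf[:, :w] += dpre @ params[f"W{ell}"].T
    return grads


@dataclass
class DenseGCNModel:
    """Trained DenseGCN: parameters plus the config that shaped them."""

    params: dict[str, np.ndarray]
    cfg: GCNConfig
    in_dim: int


def train_densegcn(data: GraphDataset, cfg: GCNConfig) -> tuple[DenseGCNModel, dict]:
    """Full-graph transductive training with best-validation model selection.

    The forward pass runs over all nodes; the loss reads only training-node
    labels. History records per-epoch training loss, training accuracy and
    validation accuracy (lengths = epochs). Reproducible given ``cfg.seed``.
    """
    train_idx = np.asarray(data.masks.train, dtype=int)
    val_idx = np.asarray(data.masks.val, dtype=int)
    y = data.labels
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training mask must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    A_norm = normalize_adjacency(data.adjacency).astype(np.dtype(cfg.dtype))
    X = np.asarray(data.features, dtype=np.dtype(cfg.dtype))
    in_dim = X.shape[1]
    params = init_params(in_dim, cfg, rng)
    opt = Adam(params, lr=cfg.learning_rate)
    n_train = len(train_idx)

    history: dict[str, list[float]] = {"train_loss": [], "train_acc": [], "val_acc": []}
    best_val = (-1.0, -np.inf)
    best_params = {k: v.copy() for k, v in params.items()}
    onehot = np.zeros((X.shape[0], 2))
    onehot[train_idx, y[train_idx]] = 1.0
    train_ind = np.zeros((X.shape[0], 1))
    train_ind[train_idx] = 1.0
    eval_agg0 = A_norm @ X  # X never changes: reuse for every eval pass

    for epoch in range(cfg.epochs):
        cache: dict = {}
        _, probs = densegcn_forward(X, A_norm, params, cfg.n_layers,
                                    dropout=cfg.dropout, rng=rng, _cache=cache)
        p_train = probs[train_idx, y[train_idx]]
        loss = float(-np.log(np.clip(p_train, 1e-12, None)).mean())
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        dlogits = (probs - onehot) * train_ind / n_train
        grads = _backward(cache, A_norm, params, cfg.n_layers, dlogits)
        opt.step(grads)

        _, eval_probs = densegcn_forward(X, A_norm, params, cfg.n_layers,
                                         _agg0=eval_agg0)
        pred = eval_probs.argmax(axis=1)
        train_acc = float((pred[train_idx] == y[train_idx]).mean())
        if len(val_idx):
            val_acc = float((pred[val_idx] == y[val_idx]).mean())
            p_val = eval_probs[val_idx, y[val_idx]]
            val_loss = float(-np.log(np.clip(p_val, 1e-12, None)).mean())
        else:
            val_acc, val_loss = 0.0, np.inf
        history["train_loss"].append(loss)
        history["train_acc"].append(train_acc)
        history["val_acc"].append(val_acc)
        # best validation accuracy; ties (common once val acc saturates)
        # broken by lower validation cross-entropy
        if (val_acc, -val_loss) > best_val:
            best_val = (val_acc, -val_loss)
            best_params = {k: v.copy() for k, v in params.items()}

    logger.info("DenseGCN trained %d epochs: loss %.4f -> %.4f, best val acc %.4f",
                cfg.epochs, history["train_loss"][0], history["train_loss"][-1], best_val[0])
    return DenseGCNModel(best_params, cfg, in_dim), history


def predict(model: DenseGCNModel, data: GraphDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-node class probabilities and hard labels from a trained model.

    Hard label = argmax of the probability row; an exact tie resolves to
    class 0 (logged with a warning).
    """
    A_norm = normalize_adjacency(data.adjacency).astype(model.params["W0"].dtype)
    X = np.asarray(data.features, dtype=model.params["W0"].dtype)
    if X.shape[1] != model.in_dim:
        raise ValueError(f"expected {model.in_dim} features, got {X.shape[1]}")
    _, probs = densegcn_forward(X, A_norm, model.params, model.cfg.n_layers)
    ties = probs[:, 0] == probs[:, 1]
    if ties.any():
        warnings.warn(f"{int(ties.sum())} exact probability tie(s) resolved to class 0",
                      stacklevel=2)
    hard = probs.argmax(axis=1)  # argmax takes the first (lower) index on ties
    return probs, hard
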