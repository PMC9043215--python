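"""Per-omic denoising autoencoders for latent feature extraction.

Each omic view, already min-max scaled to [0, 1], is compressed by an
encoder–decoder trained to reconstruct the clean matrix from a corrupted
copy (masking or Gaussian noise). The mean-squared reconstruction error is
taken against the clean input — the classical denoising objective. Encoders
are trained per omic; their latent codes are concatenated column-wise to
form the node features of the graph classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from psngcn._nn import Adam, glorot_uniform, sigmoid

logger = logging.getLogger(__name__)


@dataclass
class DAEConfig:
    """Denoising-autoencoder hyperparameters.

    Defaults: 300 latent features per omic, one 256-unit hidden layer,
    learning rate 0.01, 50 epochs, mini-batches of 8, masking noise at 0.2.
    """

    latent_dim: int = 300
    hidden_dims: tuple[int, ...] = (256,)
    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 8
    noise_kind: str = "masking"
    noise_level: float = 0.2
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("latent_dim, epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.noise_kind not in ("masking", "gaussian"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")


@dataclass
class LatentMatrix:
    """Encoder output for one omic: n samples x latent_dim columns."""

    values: np.ndarray
    sample_ids: list[str] | None = None
    omic_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("latent matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite latent values")
        if self.sample_ids is not None and len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length mismatch")


def corrupt(
    X: np.ndarray,
    noise_kind: str = "masking",
    noise_level: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Corrupt a matrix for denoising training.

    masking: each entry independently zeroed with probability ``noise_level``;
    gaussian: i.i.d. N(0, noise_level^2) added. Deterministic given seed.
    """
    X = np.asarray(X)
    if not np.isfinite(X).all():
        raise ValueError("input must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_kind == "masking":
        if not 0.0 <= noise_level <= 1.0:
            raise ValueError("masking noise_level must be in [0, 1]")
        if noise_level == 0.0:
            return X.copy()
        keep = rng.random(X.shape) >= noise_level
        return X * keep
    if noise_kind == "gaussian":
        if noise_level < 0:
            raise ValueError("gaussian noise_level must be >= 0")
        if noise_level == 0.0:
            return X.copy()
        return X + rng.normal(0.0, noise_level, size=X.shape).astype(X.dtype)
    raise ValueError(f"unknown noise_kind {noise_kind!r}")


class DenoisingAutoencoder:
    """MLP encoder/decoder with a mirrored architecture.

    Layer widths run d -> hidden_dims -> latent_dim -> reversed(hidden_dims)
    -> d. Hidden layers are ReLU, the bottleneck is linear, and the output
    layer is sigmoid so reconstructions stay bounded in (0, 1), matching the
    [0, 1]-scaled inputs. (A sigmoid bottleneck saturates within the first
    epoch at this learning rate and collapses the code to a constant.)
    """

    def __init__(self, input_dim: int, cfg: DAEConfig, rng: np.random.Generator):
        dims = [input_dim, *cfg.hidden_dims, cfg.latent_dim,
                *reversed(cfg.hidden_dims), input_dim]
        dtype = np.dtype(cfg.dtype)
        self.cfg = cfg
        self.input_dim = input_dim
        self.n_encoder_layers = len(cfg.hidden_dims) + 1
        self.n_layers = len(dims) - 1
        # encoder inputs are centered on training-column means (set during
        # training); reconstruction targets stay on the original [0, 1] scale
        self.input_mean = np.zeros(input_dim, dtype=dtype)
        self.params: dict[str, np.ndarray] = {}
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.params[f"W{i}"] = glorot_uniform(rng, a, b, dtype)
            self.params[f"b{i}"] = np.zeros(b, dtype=dtype)

    def _act(self, i: int, pre: np.ndarray) -> np.ndarray:
        if i == self.n_layers - 1:
            return sigmoid(pre)
        if i == self.n_encoder_layers - 1:
            return pre  # linear bottleneck
        return np.maximum(pre, 0.0)

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        for i in range(self.n_layers):
            acts.append(self._act(i, acts[-1] @ self.params[f"W{i}"] + self.params[f"b{i}"]))
        return acts

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.params["W0"].dtype)
        return self._forward(X - self.input_mean)[-1]

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.params["W0"].dtype)
        h = X - self.input_mean
        for i in range(self.n_encoder_layers):
            h = self._act(i, h @ self.params[f"W{i}"] + self.params[f"b{i}"])
        return h

    def _backward(self, acts: list[np.ndarray], target: np.ndarray) -> tuple[float, dict]:
        z = acts[-1]
        diff = z - target
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        grads: dict[str, np.ndarray] = {}
        delta = (2.0 / diff.size) * diff  # dL/dz
        for i in range(self.n_layers - 1, -1, -1):
            a = acts[i + 1]
            if i == self.n_layers - 1:
                dpre = delta * a * (1.0 - a)  # sigmoid'
            elif i == self.n_encoder_layers - 1:
                dpre = delta  # linear bottleneck
            else:
                dpre = delta * (a > 0)  # relu'
            grads[f"W{i}"] = acts[i].T @ dpre
            grads[f"b{i}"] = dpre.sum(axis=0)
            if i > 0:
                delta = dpre @ self.params[f"W{i}"].T
        return loss, grads


def train_dae(
    X: np.ndarray,
    cfg: DAEConfig,
) -> tuple[DenoisingAutoencoder, list[float]]:
    """Train a denoising autoencoder on an n x d matrix scaled to [0, 1].

    Per epoch the rows are shuffled into mini-batches; each batch is freshly
    corrupted and the model reconstructs the *clean* batch from the corrupted
    one under mean squared error, optimized by Adam. Encoder inputs are
    centered on the training-column means (stored on the model and re-applied
    at encode time) — without centering, the first layer is badly conditioned
    on all-positive data and code quality degrades sharply. Returns the
    trained model and the per-epoch mean training loss (length = epochs).
    Fully deterministic given ``cfg.seed``.
    """
    X = np.asarray(X, dtype=np.dtype(cfg.dtype))
    n, d = X.shape
    if cfg.latent_dim >= d:
        raise ValueError(f"latent_dim {cfg.latent_dim} must be < input dim {d}")
    if n < cfg.batch_size:
        raise ValueError(f"need at least batch_size={cfg.batch_size} samples, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("input must be finite")

    rng = np.random.default_rng(cfg.seed)
    model = DenoisingAutoencoder(d, cfg, rng)
    model.input_mean = X.mean(axis=0)
    opt = Adam(model.params, lr=cfg.learning_rate)
    losses: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            batch = X[order[start:start + cfg.batch_size]]
            noisy = corrupt(batch, cfg.noise_kind, cfg.noise_level, rng)
            noisy -= model.input_mean
            acts = model._forward(noisy)
            loss, grads = model._backward(acts, batch)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite DAE loss at epoch {epoch}: lr={cfg.learning_rate}"
                )
            opt.step(grads)
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    logger.info("DAE d=%d q=%d: loss %.5f -> %.5f over %d epochs",
                d, cfg.latent_dim, losses[0], losses[-1], cfg.epochs)
    return model, losses


def encode(
    model: DenoisingAutoencoder,
    X: np.ndarray,
    sample_ids: list[str] | None = None,
    omic_name: str = "",
) -> LatentMatrix:
    """Encode a clean (uncorrupted) matrix into its latent representation."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"expected n x {model.input_dim} input, got {X.shape}"
        )
    return LatentMatrix(model.encode(X), sample_ids=sample_ids, omic_name=omic_name)


def concat_latents(Zs: Sequence[LatentMatrix]) -> np.ndarray:
    """Column-wise concatenation of per-omic latents in the given omic order.

    All inputs must share one sample order; a mismatch raises.
    """
    if not Zs:
        raise ValueError("no latent matrices given")
    ref = Zs[0]
    for z in Zs[1:]:
        if z.values.shape[0] != ref.values.shape[0]:
            raise ValueError("latent matrices disagree on sample count")
        if ref.sample_ids is not None and z.sample_ids is not None \
                and z.sample_ids != ref.sample_ids:
            raise ValueError("sample order mismatch across latent matrices")
    return np.hstack([z.values for z in Zs])
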