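"""Synthetic multi-view omics with known class structure.

The generator emulates the shape class of multi-omic tumor/normal cohorts:
a few hundred patients, thousands of features per view, all views driven by
one low-rank latent disease state. Per sample a latent vector is drawn from
a class-conditional Gaussian (class means separated by ``class_separation``
latent standard deviations); each view observes the latent through its own
random loading matrix restricted to an informative subset of columns, plus
i.i.d. Gaussian noise, a shift into nonnegative range, and missing entries
at a fixed rate. Ground truth (latents, means, loadings) is returned so
recovery tests can compare against the generative model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass


import numpy as np

from psngcn import snf as snf_mod
from psngcn.densegcn import GraphDataset
from psngcn.pipeline import split_samples
from psngcn.preprocess import LabelVector, OmicsMatrix

logger = logging.getLogger(__name__)

OMIC_NAMES = ("rna", "meth", "cnv")


@dataclass
class SyntheticSpec:
    """Generator settings; defaults mimic a ~400-patient three-omic cohort."""

    n_samples: int = 400
    dims: tuple[int, ...] = (2000, 2000, 2400)
    latent_rank: int = 5
    class_separation: float = 4.0
    noise_sd: float | tuple[float, ...] = 0.5
    missing_rate: float = 0.05
    informative_fraction: float | tuple[float, ...] = 0.3
    latent_dims_per_omic: tuple[tuple[int, ...], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.latent_rank < 1 or self.latent_rank >= min(self.dims):
            raise ValueError("latent_rank must be in [1, min(dims))")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.latent_dims_per_omic is not None:
            for dims in self.latent_dims_per_omic:
                if any(not 0 <= d < self.latent_rank for d in dims):
                    raise ValueError("latent_dims_per_omic out of range")

    def noise_per_omic(self) -> tuple[float, ...]:
        s = self.noise_sd
        return tuple(s) if isinstance(s, (tuple, list)) else (s,) * len(self.dims)

    def frac_per_omic(self) -> tuple[float, ...]:
        f = self.informative_fraction
        return tuple(f) if isinstance(f, (tuple, list)) else (f,) * len(self.dims)


def generate_multiomics(
    spec: SyntheticSpec,
) -> tuple[list[OmicsMatrix], LabelVector, dict]:
    """Draw a multi-view cohort with shared low-rank class structure.

    Returns the per-omic matrices (missing entries as NaN), balanced binary
    labels, and a ground-truth dict with the latent matrix, class means and
    per-omic loadings.

    With ``latent_dims_per_omic`` each view observes only the listed latent
    coordinates, modelling complementary omics: no single view sees the full
    class separation, their combination does. The class-mean direction is
    then spread evenly over the latent coordinates so each view's share of
    the separation is proportional to how many coordinates it observes.
    """
    rng = np.random.default_rng(spec.seed)
    n, r = spec.n_samples, spec.latent_rank

    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    rng.shuffle(labels)

    if spec.latent_dims_per_omic is not None:
        direction = np.ones(r)  # equal share of separation per coordinate
    else:
        direction = rng.normal(size=r)
    direction /= np.linalg.norm(direction)
    mu1 = 0.5 * spec.class_separation * direction
    mu0 = -mu1
    z = np.where(labels[:, None] == 1, mu1, mu0) + rng.normal(size=(n, r))

    sample_ids = [f"S{i:04d}" for i in range(n)]
    matrices = []
    loadings = []
    noise = spec.noise_per_omic()
    fracs = spec.frac_per_omic()
    for h, d in enumerate(spec.dims):
        name = OMIC_NAMES[h] if h < len(OMIC_NAMES) else f"omic{h}"
        n_inf = max(1, int(round(fracs[h] * d)))
        cols = rng.choice(d, size=n_inf, replace=False)
        if spec.latent_dims_per_omic is not None:
            observed = list(spec.latent_dims_per_omic[h])
        else:
            observed = list(range(r))
        W = np.zeros((r, d))
        W[np.ix_(observed, cols)] = (
            rng.normal(size=(len(observed), n_inf)) / np.sqrt(len(observed))
        )
        X = z @ W + rng.normal(scale=noise[h], size=(n, d))
        X -= X.min(axis=0)  # nonnegative range, as raw omic measurements are
        if spec.missing_rate > 0:
            mask = rng.random((n, d)) < spec.missing_rate
            X[mask] = np.nan
        loadings.append(W)
        matrices.append(OmicsMatrix(
            sample_ids=list(sample_ids),
            feature_ids=[f"{name}_f{j:05d}" for j in range(d)],
            values=X,
            omic_name=name,
        ))
    truth = {"z": z, "mu0": mu0, "mu1": mu1, "loadings": loadings,
             "direction": direction}
    logger.info("generated %d-sample cohort, dims=%s, separation=%.2f",
                n, spec.dims, spec.class_separation)
    return matrices, LabelVector(list(sample_ids), labels), truth


def generate_identity_unfavorable(
    spec: SyntheticSpec,
    feature_dim: int = 50,
    feature_separation: float = 0.8,
    similarity_separation: float = 6.0,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> tuple[GraphDataset, dict]:
    """Fixture where the patient network carries the signal, not the features.

    Node features are weakly class-informative Gaussians
    (``feature_separation`` latent SDs apart), while the adjacency is a fused
    similarity network built from two auxiliary strongly separated views
    (``similarity_separation``). A graph-aware classifier should beat the
    identity-adjacency ablation here.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    rng.shuffle(labels)

    # weak features
    u = rng.normal(size=feature_dim)
    u /= np.linalg.norm(u)
    shift = 0.5 * feature_separation * u
    features = rng.normal(size=(n, feature_dim))
    features += np.where(labels[:, None] == 1, shift, -shift)

    # strongly class-aligned similarity from two auxiliary views
    K = snf_mod.default_k(n)
    Ws = []
    for _ in range(2):
        v = rng.normal(size=spec.latent_rank)
        v /= np.linalg.norm(v)
        mu = 0.5 * similarity_separation * v
        zv = np.where(labels[:, None] == 1, mu, -mu) \
            + rng.normal(size=(n, spec.latent_rank))
        D = snf_mod.pairwise_distance(zv)
        Ws.append(snf_mod.affinity_matrix(D, K=K))
    fused = snf_mod.snf_fuse(Ws, K=K, T=10).values

    masks = split_samples(n, labels, fractions, seed=spec.seed)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    data = GraphDataset(fused, features, labels, masks, sample_ids=sample_ids)
    within, between = block_similarity(fused, labels)
    truth = {"within_class_similarity": within, "between_class_similarity": between}
    return data, truth


def block_similarity(A: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Mean within-class and between-class similarity (diagonal excluded)."""
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    return float(A[same & off].mean()), float(A[~same].mean())
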