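"""End-to-end orchestration: preprocess -> SNF -> DAE -> DenseGCN -> metrics.

The evaluation protocol mirrors the study design: a random 60/20/20
train/validation/test split, five independent repeats (each re-randomizing
the split and all network initializations), and positive-class precision,
recall, F1, accuracy and AUC on the held-out test nodes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
    f1_score,
    roc_auc_score,
)

from psngcn import dae as dae_mod
from psngcn import densegcn as gcn_mod
from psngcn import preprocess as prep
from psngcn import snf as snf_mod
from psngcn.dae import DAEConfig
from psngcn.densegcn import GCNConfig, GraphDataset
from psngcn.preprocess import LabelVector, OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class SplitMasks:
    """Disjoint train/validation/test index sets covering all n samples."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.val = np.asarray(self.val, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split masks overlap")


@dataclass
class MetricsReport:
    """Positive-class precision/recall/F1, accuracy and AUC for one run."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class AggregateReport:
    """Per-repeat metric reports plus their arithmetic mean."""

    per_repeat: list[MetricsReport]
    mean: MetricsReport

    def as_dict(self) -> dict:
        return {"per_repeat": [r.as_dict() for r in self.per_repeat],
                "mean": self.mean.as_dict()}


def split_samples(
    n: int,
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    max_retries: int = 100,
) -> SplitMasks:
    """Random disjoint split with both classes required in every part.

    Sizes: train = floor(f_train * n), val = floor(f_val * n), test = rest.
    Draws are retried (bounded) until each part contains both classes.
    """
    labels = np.asarray(labels, dtype=int)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(n)
        masks = SplitMasks(perm[:n_train], perm[n_train:n_train + n_val],
                           perm[n_train + n_val:])
        if all(len(np.unique(labels[idx])) == 2
               for idx in (masks.train, masks.val, masks.test)):
            return masks
    raise ValueError(f"could not draw a both-class split in {max_retries} tries")


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_prob: np.ndarray,
) -> MetricsReport:
    """Positive-class metrics from hard predictions and positive-class scores.

    Degenerate denominators (no predicted positives, no true positives, or a
    single-class truth for AUC) yield 0 with a warning rather than an error.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if not (len(y_true) == len(y_pred) == len(y_prob)):
        raise ValueError("length mismatch")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision = float(precision_score(y_true, y_pred, zero_division=0))
        recall = float(recall_score(y_true, y_pred, zero_division=0))
        f1 = float(f1_score(y_true, y_pred, zero_division=0))
    accuracy = float(accuracy_score(y_true, y_pred))
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class truth: AUC undefined, reporting 0", stacklevel=2)
        auc = 0.0
    else:
        auc = float(roc_auc_score(y_true, y_prob))
    if precision == 0 or recall == 0:
        warnings.warn("degenerate precision/recall (no positive overlap)", stacklevel=2)
    return MetricsReport(precision, recall, f1, accuracy, auc)


@dataclass
class PipelineConfig:
    """All knobs for one end-to-end run.

    ``snf_k`` of None means the data-driven default max(3, round(n/10)).
    ``identity_adjacency`` replaces the fused patient network by the identity
    matrix, the graph-free ablation.
    """

    snf_alpha: float = 0.5
    snf_k: int | None = None
    snf_iters: int = 20
    dae: DAEConfig = field(default_factory=DAEConfig)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    feature_frac: float = 0.2
    sample_frac: float = 0.2
    identity_adjacency: bool = False
    seed: int = 0
    outdir: str | Path | None = None


def _replace_seed(cfg, seed: int):
    from dataclasses import replace
    return replace(cfg, seed=seed)


def build_adjacency(
    normalized: Sequence[OmicsMatrix],
    cfg: PipelineConfig,
) -> np.ndarray:
    """Fused patient similarity network from the normalized full matrices.

    A single view skips fusion (the cross-diffusion update needs m >= 2) and
    uses that view's fully normalized affinity P, symmetrized, instead.
    """
    n = normalized[0].n_samples
    K = cfg.snf_k if cfg.snf_k is not None else snf_mod.default_k(n)
    Ws = []
    for m in normalized:
        D = snf_mod.pairwise_distance(m.values)
        Ws.append(snf_mod.affinity_matrix(D, K=K, alpha=cfg.snf_alpha,
                                          sample_ids=list(m.sample_ids)))
    if len(Ws) == 1:
        P = snf_mod.normalize_full(Ws[0]).values
        return (P + P.T) / 2.0
    return snf_mod.snf_fuse(Ws, K=K, T=cfg.snf_iters).values


def run_pipeline(
    matrices: Sequence[OmicsMatrix],
    labels: LabelVector,
    cfg: PipelineConfig,
) -> tuple[MetricsReport, dict]:
    """One full run; returns test-set metrics and a dict of stage artifacts.

    Stages: clean/normalize each omic, intersect samples, split 60/20/20,
    build the fused patient network (all-sample, unsupervised), train one DAE
    per omic on training samples only, encode all samples, concatenate
    latents, train the DenseGCN transductively, score the test nodes.
    """
    normalized, labels, summary = prep.preprocess_all(
        matrices, labels, cfg.feature_frac, cfg.sample_frac
    )
    n = normalized[0].n_samples
    y = labels.labels
    masks = split_samples(n, y, cfg.fractions, seed=cfg.seed)

    if cfg.identity_adjacency:
        adjacency = np.eye(n)
    else:
        adjacency = build_adjacency(normalized, cfg)

    # per-omic DAEs: fit on training rows only, encode everything
    seeder = np.random.default_rng(cfg.seed)
    latents = []
    for m in normalized:
        sub_seed = int(seeder.integers(0, 2**31 - 1))
        dcfg = _replace_seed(cfg.dae, sub_seed)
        model, losses = dae_mod.train_dae(m.values[masks.train], dcfg)
        latents.append(dae_mod.encode(model, m.values,
                                      sample_ids=list(m.sample_ids),
                                      omic_name=m.omic_name))
    features = dae_mod.concat_latents(latents)

    gcfg = _replace_seed(cfg.gcn, int(seeder.integers(0, 2**31 - 1)))
    data = GraphDataset(adjacency, features, y, masks,
                        sample_ids=list(normalized[0].sample_ids))
    model, history = gcn_mod.train_densegcn(data, gcfg)
    probs, hard = gcn_mod.predict(model, data)
    report = compute_metrics(y[masks.test], hard[masks.test], probs[masks.test, 1])

    artifacts = {
        "preprocess_summary": summary,
        "masks": masks,
        "adjacency": adjacency,
        "features": features,
        "history": history,
        "probs": probs,
        "pred": hard,
        "sample_ids": list(normalized[0].sample_ids),
    }
    if cfg.outdir is not None:
        _write_artifacts(cfg, report, artifacts)
    return report, artifacts


def _write_artifacts(cfg: PipelineConfig, report: MetricsReport, artifacts: dict) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ids = artifacts["sample_ids"]
    pd.DataFrame(artifacts["adjacency"], index=ids, columns=ids).to_csv(
        out / "fused_network.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(artifacts["features"], index=ids).to_csv(
        out / "node_features.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame({
        "sample_id": ids,
        "prob_tumor": artifacts["probs"][:, 1],
        "predicted": artifacts["pred"],
    }).to_csv(out / "predictions.tsv", sep="\t", index=False)
    manifest = {
        "config": {
            "snf_alpha": cfg.snf_alpha, "snf_k": cfg.snf_k, "snf_iters": cfg.snf_iters,
            "dae": asdict(cfg.dae), "gcn": asdict(cfg.gcn),
            "fractions": list(cfg.fractions), "seed": cfg.seed,
            "identity_adjacency": cfg.identity_adjacency,
        },
        "preprocess": artifacts["preprocess_summary"],
        "metrics": report.as_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _aggregate(reports: list[MetricsReport]) -> AggregateReport:
    mean = MetricsReport(**{
        k: float(np.mean([r.as_dict()[k] for r in reports]))
        for k in reports[0].as_dict()
    })
    return AggregateReport(reports, mean)


def repeat_experiments(
    matrices: Sequence[OmicsMatrix],
    labels: LabelVector,
    cfg: PipelineConfig,
    repeats: int = 5,
) -> AggregateReport:
    """Run the pipeline ``repeats`` times with seeds seed+0 ... seed+repeats-1.

    Every repeat re-randomizes the split and all network initializations; the
    aggregate reports per-repeat metrics and their arithmetic mean.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    reports = []
    for i in range(repeats):
        run_cfg = _replace_seed(cfg, cfg.seed + i)
        report, _ = run_pipeline(matrices, labels, run_cfg)
        logger.info("repeat %d/%d: acc=%.4f auc=%.4f", i + 1, repeats,
                    report.accuracy, report.auc)
        reports.append(report)
    return _aggregate(reports)


def run_ablation(
    matrices: Sequence[OmicsMatrix],
    labels: LabelVector,
    cfg: PipelineConfig,
    mode: str = "psn",
    repeats: int = 5,
) -> dict[str, AggregateReport]:
    """Matched-seed ablations over the adjacency or the omic subset.

    mode="psn" compares the fused patient network against the identity
    adjacency; mode="omics" enumerates all non-empty subsets of the given
    omics. Everything else (seeds, splits, hyperparameters) is held fixed.
    """
    from dataclasses import replace

    results: dict[str, AggregateReport] = {}
    if mode == "psn":
        for name, flag in (("psn", False), ("identity", True)):
            variant = replace(cfg, identity_adjacency=flag, outdir=None)
            results[name] = repeat_experiments(matrices, labels, variant, repeats)
    elif mode == "omics":
        names = [m.omic_name or f"omic{i}" for i, m in enumerate(matrices)]
        for r in range(1, len(matrices) + 1):
            for combo in combinations(range(len(matrices)), r):
                key = "+".join(names[i] for i in combo)
                subset = [matrices[i] for i in combo]
                variant = replace(cfg, outdir=None)
                results[key] = repeat_experiments(subset, labels, variant, repeats)
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    return results


def run_graph_ablation(
    data: GraphDataset,
    gcn_cfg: GCNConfig,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    repeats: int = 5,
    seed: int = 0,
) -> dict[str, AggregateReport]:
    """PSN-vs-identity comparison on a prebuilt graph dataset.

    For each repeat one split is drawn and both adjacency variants are
    trained on it with the same initialization seed — the matched design the
    graph-ablation question needs.
    """
    from dataclasses import replace

    n = data.adjacency.shape[0]
    results: dict[str, list[MetricsReport]] = {"psn": [], "identity": []}
    for i in range(repeats):
        masks = split_samples(n, data.labels, fractions, seed=seed + i)
        run_cfg = replace(gcn_cfg, seed=seed + i)
        for name, adj in (("psn", data.adjacency), ("identity", np.eye(n))):
            variant = GraphDataset(adj, data.features, data.labels, masks,
                                   sample_ids=data.sample_ids)
            model, _ = gcn_mod.train_densegcn(variant, run_cfg)
            probs, hard = gcn_mod.predict(model, variant)
            results[name].append(compute_metrics(
                data.labels[masks.test], hard[masks.test], probs[masks.test, 1]))
    return {k: _aggregate(v) for k, v in results.items()}
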