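"""Loading, alignment, filtering, imputation and normalization of omic matrices.

Each omic arrives as a delimited samples-by-features matrix with possible
missing entries. The cleaning pipeline is: drop features with too many missing
values, then drop samples with too many missing values over the surviving
features, intersect sample sets across omics, impute remaining gaps with the
per-feature mean, and min-max scale every feature to [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as missing when parsing delimited matrices.
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "null")


@dataclass
class OmicsMatrix:
    """One omic view: an n-samples x d-features real matrix.

    Missing entries are stored as NaN in ``values``; :attr:`missing_mask`
    derives from that. Sample and feature identifiers must be unique.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    omic_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != d:
            raise ValueError("duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean n x d mask, True where the entry is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class LabelVector:
    """Binary diagnosis labels (1 = tumor, 0 = normal) keyed by sample id."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must be one integer per sample id")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in labels")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def subset(self, sample_ids: Sequence[str]) -> "LabelVector":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample ids absent from labels: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return LabelVector(list(sample_ids), self.labels[rows])


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_omics(
    path: str | Path,
    omic_name: str = "",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> OmicsMatrix:
    """Read a delimited samples-by-features matrix.

    The file must have a header row of feature ids and a first column of
    sample ids; cells matching ``missing_tokens`` become missing entries.
    Duplicate sample ids or non-numeric cells raise ``ValueError``.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(
        path,
        sep=_detect_sep(path),
        index_col=0,
        dtype=str,
        na_values=list(missing_tokens),
        keep_default_na=False,
        skip_blank_lines=True,
    )
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell outside missing tokens: {exc}") from exc
    m = OmicsMatrix(
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=values,
        omic_name=omic_name or path.stem,
    )
    logger.info(
        "loaded %s: %d samples x %d features, %d missing entries",
        m.omic_name, m.n_samples, m.n_features, m.n_missing,
    )
    return m


def save_omics(m: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    m.to_frame().to_csv(path, sep=_detect_sep_for_write(path), index_label="sample_id")


def _detect_sep_for_write(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_labels(path: str | Path) -> LabelVector:
    """Read a two-column (sample_id, label) delimited file; header optional."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, label)")
    first_label = str(df.iloc[0, 1]).strip()
    if first_label not in {"0", "1"}:  # header row
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no label rows")
    return LabelVector(
        sample_ids=[str(s) for s in df.iloc[:, 0]],
        labels=df.iloc[:, 1].astype(int).to_numpy(),
    )


def save_labels(labels: LabelVector, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep=_detect_sep_for_write(path), index=False
    )


def filter_missing(
    m: OmicsMatrix,
    feature_frac: float = 0.2,
    sample_frac: float = 0.2,
) -> OmicsMatrix:
    """Drop features, then samples, with too many missing values.

    A feature is removed when strictly more than ``feature_frac`` of its
    entries are missing; afterwards a sample is removed when strictly more
    than ``sample_frac`` of the *surviving* features are missing.
    """
    mask = m.missing_mask
    feat_keep = mask.mean(axis=0) <= feature_frac
    if not feat_keep.any():
        raise ValueError(f"{m.omic_name}: all features exceed missing fraction {feature_frac}")
    values = m.values[:, feat_keep]
    sample_keep = np.isnan(values).mean(axis=1) <= sample_frac
    if not sample_keep.any():
        raise ValueError(f"{m.omic_name}: all samples exceed missing fraction {sample_frac}")
    logger.info(
        "%s: filtered %d/%d features and %d/%d samples",
        m.omic_name,
        int((~feat_keep).sum()), m.n_features,
        int((~sample_keep).sum()), m.n_samples,
    )
    return OmicsMatrix(
        sample_ids=[s for s, k in zip(m.sample_ids, sample_keep) if k],
        feature_ids=[f for f, k in zip(m.feature_ids, feat_keep) if k],
        values=values[sample_keep],
        omic_name=m.omic_name,
    )


def intersect_samples(
    matrices: Sequence[OmicsMatrix],
    labels: LabelVector,
) -> tuple[list[OmicsMatrix], LabelVector]:
    """Restrict all omics and labels to their common samples, sorted by id.

    The canonical shared order is the sorted intersection of all sample id
    sets, which makes downstream runs independent of input file ordering.
    """
    if len(matrices) < 1:
        raise ValueError("need at least one matrix")
    common: set[str] = set(labels.sample_ids)
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no common samples across omics and labels")
    order = sorted(common)
    out = []
    for m in matrices:
        index = {s: i for i, s in enumerate(m.sample_ids)}
        rows = [index[s] for s in order]
        out.append(
            OmicsMatrix(list(order), list(m.feature_ids), m.values[rows], m.omic_name)
        )
    logger.info("intersection retains %d common samples", len(order))
    return out, labels.subset(order)


def impute_mean(m: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing entry by the observed mean of its feature column."""
    values = m.values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return OmicsMatrix(list(m.sample_ids), list(m.feature_ids), values, m.omic_name)
    all_missing = mask.all(axis=0)
    if all_missing.any():
        bad = [m.feature_ids[i] for i in np.flatnonzero(all_missing)[:5]]
        raise ValueError(f"{m.omic_name}: fully missing feature columns {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(values, axis=0)
    values[mask] = np.take(col_means, np.nonzero(mask)[1])
    logger.info("%s: imputed %d entries", m.omic_name, int(mask.sum()))
    return OmicsMatrix(list(m.sample_ids), list(m.feature_ids), values, m.omic_name)


def minmax_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Scale each feature to [0, 1] via (X - X_min) / (X_max - X_min).

    Constant columns (zero range) map to all-zero, with a warning: the
    normalization is undefined (0/0) there and a constant feature carries no
    information anyway.
    """
    if not np.isfinite(m.values).all():
        raise ValueError(f"{m.omic_name}: non-finite values; impute before normalizing")
    lo = m.values.min(axis=0)
    hi = m.values.max(axis=0)
    rng = hi - lo
    constant = rng == 0
    if constant.any():
        warnings.warn(
            f"{m.omic_name or 'omics'}: {int(constant.sum())} constant feature(s) "
            "normalized to 0",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, rng)
    values = (m.values - lo) / safe
    values[:, constant] = 0.0
    return OmicsMatrix(list(m.sample_ids), list(m.feature_ids), values, m.omic_name)


def preprocess_all(
    matrices: Sequence[OmicsMatrix],
    labels: LabelVector,
    feature_frac: float = 0.2,
    sample_frac: float = 0.2,
) -> tuple[list[OmicsMatrix], LabelVector, dict]:
    """Run the full cleaning chain: filter -> intersect -> impute -> normalize.

    Returns the analysis-ready matrices, aligned labels and a JSON-able
    summary of per-omic filtering and imputation counts.
    """
    summary: dict = {"omics": {}}
    filtered = []
    for m in matrices:
        f = filter_missing(m, feature_frac, sample_frac)
        summary["omics"][f.omic_name] = {
            "features_in": m.n_features,
            "features_kept": f.n_features,
            "samples_in": m.n_samples,
            "samples_kept": f.n_samples,
        }
        filtered.append(f)
    aligned, labels = intersect_samples(filtered, labels)
    summary["common_samples"] = aligned[0].n_samples
    out = []
    for m in aligned:
        summary["omics"][m.omic_name]["imputed_entries"] = m.n_missing
        out.append(minmax_normalize(impute_mean(m)))
    return out, labels, summary
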