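import numpy as np
import pytest

from psngcn.preprocess import LabelVector, OmicsMatrix
from psngcn.synthetic_data import SyntheticSpec, generate_multiomics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny three-omic cohort with clear class structure (fast, shared)."""
    spec = SyntheticSpec(n_samples=60, dims=(80, 80, 90), latent_rank=3,
                         class_separation=4.0, missing_rate=0.05, seed=11)
    return generate_multiomics(spec)


def make_omics(values, omic_name="test", sample_prefix="s", feature_prefix="f"):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return OmicsMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        feature_ids=[f"{feature_prefix}{j}" for j in range(d)],
        values=values,
        omic_name=omic_name,
    )


def make_labels(sample_ids, labels):
    return LabelVector(list(sample_ids), np.asarray(labels, dtype=int))
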