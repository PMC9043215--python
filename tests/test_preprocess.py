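import numpy as np
import pytest

from psngcn import preprocess as prep
from psngcn.preprocess import (
    OmicsMatrix,
    filter_missing,
    impute_mean,
    intersect_samples,
    load_labels,
    load_omics,
    minmax_normalize,
    preprocess_all,
)

from conftest import make_labels, make_omics


class TestLoadOmics:
    def test_na_cell_becomes_missing(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tf1\tf2\ns1\t1.0\t2.0\ns2\tNA\t3.0\ns3\t4.0\t5.0\n")
        m = load_omics(p, "rna")
        assert m.values.shape == (3, 2)
        assert m.n_missing == 1
        assert np.isnan(m.values[1, 0])

    def test_all_missing_tokens_recognized(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,f1,f2\ns1,NaN,null\ns2,,1.5\n")
        m = load_omics(p)
        assert m.n_missing == 3

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tf1\ns1\t1.0\ns1\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_omics(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            load_omics(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tf1\ns1\thello\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_omics(p)

    def test_roundtrip(self, tmp_path):
        m = make_omics([[1.0, 2.0], [np.nan, 4.0]])
        prep.save_omics(m, tmp_path / "m.tsv")
        back = load_omics(tmp_path / "m.tsv")
        assert back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(m.values))


class TestLabels:
    def test_load_with_header(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("sample_id\tlabel\ns1\t1\ns2\t0\n")
        lv = load_labels(p)
        assert lv.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(lv.labels, [1, 0])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            make_labels(["a", "b"], [0, 2])


class TestFilterMissing:
    def test_feature_over_threshold_removed(self):
        # feature 2 missing in 3/10 samples (30% > 20%) -> dropped
        v = np.ones((10, 5))
        v[:3, 2] = np.nan
        out = filter_missing(make_omics(v))
        assert out.n_features == 4
        assert "f2" not in out.feature_ids

    def test_no_missing_is_identity(self):
        m = make_omics(np.arange(12.0).reshape(3, 4))
        out = filter_missing(m)
        assert out.feature_ids == m.feature_ids
        assert out.sample_ids == m.sample_ids
        np.testing.assert_array_equal(out.values, m.values)

    def test_sample_over_threshold_removed_after_features(self):
        # 10 samples x 8 features; sample 0 missing 2/8 = 25% -> dropped
        v = np.ones((10, 8))
        v[0, :2] = np.nan
        out = filter_missing(make_omics(v))
        assert out.n_features == 8  # each feature only 10% missing
        assert out.n_samples == 9
        assert "s0" not in out.sample_ids

    def test_exact_threshold_survives(self):
        # strict ">": exactly 20% missing stays
        v = np.ones((10, 5))
        v[:2, 1] = np.nan
        out = filter_missing(make_omics(v))
        assert out.n_features == 5

    def test_all_features_removed_errors(self):
        v = np.full((4, 3), np.nan)
        with pytest.raises(ValueError):
            filter_missing(make_omics(v))

    def test_never_adds_missing_entries_to_survivors(self, rng):
        # filtering only removes rows/columns: a surviving feature's count
        # of missing entries can only shrink, and none are introduced
        v = rng.random((30, 20))
        v[rng.random((30, 20)) < 0.15] = np.nan
        m = make_omics(v)
        before = {f: c for f, c in
                  zip(m.feature_ids, m.missing_mask.sum(axis=0))}
        out = filter_missing(m)
        for f, count in zip(out.feature_ids, out.missing_mask.sum(axis=0)):
            assert count <= before[f]


class TestIntersectSamples:
    def test_common_samples_sorted(self):
        a = OmicsMatrix(["a", "b", "c"], ["f0"], [[1.0], [2.0], [3.0]], "x")
        b = OmicsMatrix(["d", "c", "b"], ["g0"], [[9.0], [8.0], [7.0]], "y")
        labels = make_labels(["a", "b", "c", "d"], [0, 1, 0, 1])
        (oa, ob), ol = intersect_samples([a, b], labels)
        assert oa.sample_ids == ob.sample_ids == ["b", "c"]
        np.testing.assert_array_equal(oa.values[:, 0], [2.0, 3.0])
        np.testing.assert_array_equal(ob.values[:, 0], [7.0, 8.0])
        np.testing.assert_array_equal(ol.labels, [1, 0])

    def test_identical_sets_keep_membership(self):
        a = make_omics([[1.0], [2.0]])
        b = make_omics([[3.0], [4.0]])
        labels = make_labels(["s0", "s1"], [0, 1])
        (oa, ob), _ = intersect_samples([a, b], labels)
        assert set(oa.sample_ids) == {"s0", "s1"}

    def test_disjoint_sets_error(self):
        a = OmicsMatrix(["a"], ["f0"], [[1.0]], "x")
        b = OmicsMatrix(["b"], ["f0"], [[1.0]], "y")
        labels = make_labels(["a", "b"], [0, 1])
        with pytest.raises(ValueError, match="common"):
            intersect_samples([a, b], labels)


class TestImputeMean:
    def test_column_mean_fills_gap(self):
        m = make_omics([[1.0], [np.nan], [3.0]])
        out = impute_mean(m)
        np.testing.assert_allclose(out.values[:, 0], [1.0, 2.0, 3.0])
        assert out.n_missing == 0

    def test_no_missing_identity(self):
        m = make_omics([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(impute_mean(m).values, m.values)

    def test_all_missing_column_errors(self):
        m = make_omics([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="fully missing"):
            impute_mean(m)


class TestMinmaxNormalize:
    def test_column_maps_to_unit_interval(self):
        m = make_omics(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(minmax_normalize(m).values[:, 0], [0.0, 0.5, 1.0])

    def test_already_unit_interval_unchanged(self):
        m = make_omics(np.array([[0.0], [0.25], [1.0]]))
        np.testing.assert_allclose(minmax_normalize(m).values, m.values)

    def test_constant_column_to_zero_with_warning(self):
        m = make_omics(np.array([[5.0], [5.0], [5.0]]))
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(m)
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0, 0.0])

    def test_non_finite_rejected(self):
        m = make_omics(np.array([[np.nan], [1.0]]))
        with pytest.raises(ValueError):
            minmax_normalize(m)

    def test_idempotent_and_exact_range(self, rng):
        m = make_omics(rng.normal(size=(20, 7)) * 10 + 3)
        once = minmax_normalize(m)
        twice = minmax_normalize(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert np.all(once.values.min(axis=0) == 0.0)
        assert np.all(once.values.max(axis=0) == 1.0)


def test_preprocess_all_chain(small_cohort):
    matrices, labels, _ = small_cohort
    cleaned, out_labels, summary = preprocess_all(matrices, labels)
    for m in cleaned:
        assert m.n_missing == 0
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0
        assert m.sample_ids == cleaned[0].sample_ids
    assert summary["common_samples"] == cleaned[0].n_samples
    assert len(out_labels.labels) == cleaned[0].n_samples
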