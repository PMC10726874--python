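"""Normalization and filtering contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gerotarget import preprocess
from gerotarget.preprocess import (
    ExpressionStudy,
    PreprocessError,
    filter_protein_coding,
    filter_zero_coverage,
    quantile_normalize,
    upper_quartile_normalize,
    vsn_transform,
)

from conftest import make_study


class TestQuantileNormalize:
    def test_hand_computed_two_by_two(self):
        # columns (1,3) and (2,4): sorted-row means are (1.5, 3.5)
        study = make_study(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = quantile_normalize(study).matrix.to_numpy()
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_unchanged(self):
        col = np.array([2.0, 5.0, 1.0, 7.0])
        study = make_study(np.column_stack([col, col, col]))
        out = quantile_normalize(study).matrix.to_numpy()
        np.testing.assert_allclose(out, np.column_stack([col, col, col]))

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(float, (7, 4),
               elements=st.floats(-50, 50, allow_nan=False), unique=True)
    )
    def test_columns_share_sorted_multiset(self, X):
        # exact multiset equality holds for tie-free columns
        out = quantile_normalize(make_study(X)).matrix.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_ties_receive_mean_of_tied_row_means(self):
        # column 2 has a tie at rank (1,2): value = mean of row means 1 and 2
        X = np.column_stack([[1.0, 2.0, 9.0], [3.0, 3.0, 6.0]])
        out = quantile_normalize(make_study(X)).matrix.to_numpy()
        # sorted-row means are (2, 2.5, 7.5); the tied pair gets mean(2, 2.5)
        np.testing.assert_allclose(out[:, 0], [2.0, 2.5, 7.5])
        np.testing.assert_allclose(out[:, 1], [2.25, 2.25, 7.5])

    def test_preserves_within_column_order(self):
        X = np.array([[5.0, 1.0], [1.0, 5.0], [3.0, 3.0]])
        out = quantile_normalize(make_study(X)).matrix.to_numpy()
        assert (np.argsort(out, axis=0) == np.argsort(X, axis=0)).all()

    def test_single_sample_rejected(self):
        with pytest.raises(PreprocessError):
            quantile_normalize(make_study(np.ones((3, 1))))

    def test_idempotent(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        once = quantile_normalize(make_study(X))
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.matrix.to_numpy(), twice.matrix.to_numpy(), atol=1e-12
        )


class TestUpperQuartile:
    def test_scale_factors_from_uq_4_and_8(self):
        # nonzero upper quartiles 4 and 8 -> mean 6 -> factors 1.5 and 0.75
        c1 = np.array([1.0, 2.0, 3.0, 4.0])
        c2 = 2 * c1
        out = upper_quartile_normalize(make_study(np.column_stack([c1, c2])))
        np.testing.assert_allclose(out.matrix.to_numpy()[:, 0], c1 * 1.5)
        np.testing.assert_allclose(out.matrix.to_numpy()[:, 1], c2 * 0.75)

    def test_equal_uq_columns_unchanged(self):
        X = np.column_stack([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        out = upper_quartile_normalize(make_study(X)).matrix.to_numpy()
        np.testing.assert_allclose(out, X)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 10, (30, 3))
        scaled = X.copy()
        scaled[:, 1] *= 7.0
        a = upper_quartile_normalize(make_study(X)).matrix.to_numpy()
        b = upper_quartile_normalize(make_study(scaled)).matrix.to_numpy()
        np.testing.assert_allclose(a[:, 1] / a[:, 1].mean(), b[:, 1] / b[:, 1].mean())

    def test_zero_upper_quartile_names_sample(self):
        X = np.zeros((4, 2))
        X[:, 0] = [1, 2, 3, 4]
        with pytest.raises(PreprocessError, match="s001"):
            upper_quartile_normalize(make_study(X))


class TestVsn:
    def test_requires_proteomics(self):
        with pytest.raises(PreprocessError):
            vsn_transform(make_study(np.ones((3, 2)), platform="rnaseq"))

    def test_monotone_per_sample(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(3, 1, (50, 4))
        out = vsn_transform(make_study(X, platform="proteomics")).matrix.to_numpy()
        for j in range(4):
            order = np.argsort(X[:, j])
            assert (np.diff(out[order, j]) >= -1e-12).all()

    def test_constant_matrix_stays_constant(self):
        out = vsn_transform(make_study(np.full((5, 3), 7.0), platform="proteomics"))
        assert np.ptp(out.matrix.to_numpy()) < 1e-9

    def test_large_values_approach_log2_differences(self):
        X = np.column_stack([[1e3, 4e3, 1.6e4], [1e3, 4e3, 1.6e4]])
        out = vsn_transform(make_study(X, platform="proteomics")).matrix.to_numpy()
        diffs = np.diff(out[:, 0])
        np.testing.assert_allclose(diffs, [2.0, 2.0], atol=1e-3)


class TestFilters:
    def test_zero_in_quarter_of_samples_removed(self):
        X = np.ones((2, 4))
        X[0, 0] = 0.0  # zero in 1 of 4 samples = 25% -> removed
        out = filter_zero_coverage(make_study(X))
        assert list(out.gene_ids) == ["G00001"]

    def test_zero_in_fifth_of_samples_retained(self):
        X = np.ones((1, 5))
        X[0, 0] = 0.0  # 20% < 25%
        out = filter_zero_coverage(make_study(X))
        assert len(out.gene_ids) == 1

    def test_no_zeros_retained_and_idempotent(self):
        X = np.random.default_rng(3).uniform(1, 5, (10, 4))
        once = filter_zero_coverage(make_study(X))
        assert once.matrix.shape[0] == 10
        twice = filter_zero_coverage(once)
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)

    def test_protein_coding_filter_counts(self):
        study = make_study(np.ones((5, 3)))
        ann = {
            "G00000": "protein_coding",
            "G00001": "lincRNA",
            "G00002": "protein_coding",
            "G00003": "pseudogene",
            "G00004": "protein_coding",
        }
        out = filter_protein_coding(study, ann)
        assert list(out.gene_ids) == ["G00000", "G00002", "G00004"]

    def test_protein_coding_empty_annotation_rejected(self):
        with pytest.raises(PreprocessError):
            filter_protein_coding(make_study(np.ones((2, 2))), {})

    def test_filters_never_reorder_samples(self):
        study = make_study(np.random.default_rng(4).uniform(1, 2, (6, 5)))
        for op in (filter_zero_coverage, quantile_normalize, upper_quartile_normalize):
            assert list(op(study).matrix.columns) == list(study.matrix.columns)


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        study = make_study(np.random.default_rng(5).normal(size=(8, 4)))
        preprocess.write_expression_tsv(study, tmp_path / "m.tsv", tmp_path / "s.tsv")
        back = preprocess.read_expression_tsv(tmp_path / "m.tsv", tmp_path / "s.tsv")
        np.testing.assert_allclose(back.matrix.to_numpy(), study.matrix.to_numpy())
        assert list(back.samples["sample_id"]) == list(study.samples["sample_id"])
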