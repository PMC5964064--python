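"""Data model, CSV round-trips, fill-fraction arithmetic, splits and descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from sparsemt.matrix import (
    ActivityMatrix,
    FingerprintSet,
    describe,
    fill_fraction,
    fill_fraction_from_counts,
    read_activity_csv,
    read_fingerprint_csv,
    tanimoto_matrix,
    train_test_split,
    write_activity_csv,
    write_fingerprint_csv,
)


class TestActivityMatrixInvariants:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ActivityMatrix(np.zeros((2, 2)), np.ones((2, 3), bool),
                           ["a", "b"], ["x", "y"], "regression")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ActivityMatrix(np.zeros((2, 1)), np.ones((2, 1), bool),
                           ["a", "a"], ["x"], "regression")

    def test_classification_values_restricted(self):
        with pytest.raises(ValueError, match="0, 1"):
            ActivityMatrix(np.array([[0.5]]), np.ones((1, 1), bool),
                           ["a"], ["x"], "classification")

    def test_nan_at_observed_cell_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            ActivityMatrix(np.array([[np.nan]]), np.ones((1, 1), bool),
                           ["a"], ["x"], "regression")


class TestCsvIO:
    def test_empty_cell_counts_as_missing(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("compound_id,a1,a2\nc1,1.5,2\nc2,,3\nc3,4,5\n")
        mat = read_activity_csv(p, "regression")
        assert mat.n_observed == 5
        assert not mat.observed[1, 0]

    def test_classification_tokens_mapped(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("compound_id,a1,a2\nc1,active,inactive\nc2,1,0\n")
        mat = read_activity_csv(p, "classification")
        assert mat.values[0, 0] == 1 and mat.values[0, 1] == 0
        assert mat.values[1, 0] == 1 and mat.values[1, 1] == 0

    def test_unknown_token_and_non_numeric_name_the_cell(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("compound_id,a1\nc1,maybe\n")
        with pytest.raises(ValueError, match="c1.*a1|a1.*c1"):
            read_activity_csv(p, "classification")
        with pytest.raises(ValueError, match="c1"):
            read_activity_csv(p, "regression")

    def test_na_token_rejected_for_regression(self, tmp_path):
        # missing means the empty string only; spreadsheet NA tokens error
        p = tmp_path / "m.csv"
        p.write_text("compound_id,a1\nc1,NA\n")
        with pytest.raises(ValueError):
            read_activity_csv(p, "regression")

    def test_duplicate_compound_rows_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("compound_id,a1\nc1,1\nc1,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_activity_csv(p, "regression")

    @pytest.mark.parametrize("fixture", ["small_regression", "small_classification"])
    def test_round_trip_identity(self, fixture, request, tmp_path):
        mat = request.getfixturevalue(fixture)
        p = tmp_path / "m.csv"
        write_activity_csv(mat, p)
        back = read_activity_csv(p, mat.task_type)
        assert back.compound_ids == mat.compound_ids
        assert back.assay_ids == mat.assay_ids
        assert np.array_equal(back.observed, mat.observed)
        assert np.allclose(back.values[back.observed], mat.values[mat.observed])

    def test_fingerprint_round_trip(self, small_fps, tmp_path):
        p = tmp_path / "f.csv"
        write_fingerprint_csv(small_fps, p)
        back = read_fingerprint_csv(p)
        assert np.array_equal(back.bits, small_fps.bits)
        assert back.compound_ids == small_fps.compound_ids


class TestFillFraction:
    def test_sums_to_100(self, small_regression):
        filled, missing = fill_fraction(small_regression)
        assert filled + missing == 100.0

    def test_fully_observed(self, full_matrix_10x10):
        filled, missing = fill_fraction(full_matrix_10x10)
        assert missing == 0.0 and filled == 100.0

    def test_pkis_scale_missing_percent(self):
        _, missing = fill_fraction_from_counts(367, 454, 367 * 454 - 87)
        assert round(missing, 2) == 0.05

    def test_recommender_scale_filled_percent(self):
        # computed from counts: a 480k x 17k grid is never materialized
        filled, _ = fill_fraction_from_counts(480_000, 17_000, 100_000_000)
        assert round(filled, 1) == 1.2

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="empty"):
            fill_fraction_from_counts(0, 10, 0)


class TestTrainTestSplit:
    def test_pkis_sized_three_to_one(self):
        rng = np.random.default_rng(0)
        mat = ActivityMatrix(rng.normal(size=(367, 5)), np.ones((367, 5), bool),
                             [f"c{i}" for i in range(367)],
                             [f"a{j}" for j in range(5)], "regression")
        res = train_test_split(mat, 0.25, seed=0)
        assert res.test.n_compounds == 92
        assert res.train.n_compounds == 275

    def test_exact_three_to_one_on_four(self, small_regression):
        res = train_test_split(small_regression, 0.25, seed=3)
        assert res.test.n_compounds == 1 and res.train.n_compounds == 3

    def test_partition_and_determinism(self, full_matrix_10x10):
        r1 = train_test_split(full_matrix_10x10, 0.3, seed=5)
        r2 = train_test_split(full_matrix_10x10, 0.3, seed=5)
        assert r1.train.compound_ids == r2.train.compound_ids
        assert r1.test.compound_ids == r2.test.compound_ids
        joint = set(r1.train.compound_ids) | set(r1.test.compound_ids)
        assert joint == set(full_matrix_10x10.compound_ids)
        assert not set(r1.train.compound_ids) & set(r1.test.compound_ids)

    def test_columns_unchanged(self, full_matrix_10x10):
        res = train_test_split(full_matrix_10x10, 0.25, seed=1)
        assert res.train.assay_ids == full_matrix_10x10.assay_ids

    def test_degenerate_split_rejected(self, small_regression):
        with pytest.raises(ValueError):
            train_test_split(small_regression, 0.01, seed=0)

    def test_fingerprints_partitioned_alongside(self, small_regression, small_fps):
        res, ftr, fte = train_test_split(small_regression, 0.25, seed=2, fps=small_fps)
        assert ftr.compound_ids == res.train.compound_ids
        assert fte.compound_ids == res.test.compound_ids


class TestTanimoto:
    def test_identical_and_disjoint(self):
        a = np.array([[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0]], dtype=np.uint8)
        sim = tanimoto_matrix(a)
        assert sim[0, 2] == 1.0
        assert sim[0, 1] == 0.0

    def test_three_fingerprint_mean_matches_hand_computation(self):
        # pairs: T(a,b)=1/3, T(a,c)=2/3, T(b,c)=2/3 -> mean 5/9
        bits = np.array([
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 1, 1, 0],
        ], dtype=np.uint8)
        sim = tanimoto_matrix(bits)
        iu = np.triu_indices(3, 1)
        assert np.isclose(sim[iu].mean(), 5.0 / 9.0)

    @settings(deadline=None, max_examples=50)
    @given(hst.integers(0, 2**12 - 1), hst.integers(1, 2**12 - 1))
    def test_symmetric_bounded_and_reflexive(self, x, y):
        a = np.array([int(c) for c in format(x, "012b")], dtype=np.uint8)
        b = np.array([int(c) for c in format(y, "012b")], dtype=np.uint8)
        sim = tanimoto_matrix(np.vstack([a, b]))
        assert sim[0, 1] == sim[1, 0]
        assert 0.0 <= sim[0, 1] <= 1.0
        if b.any():
            assert sim[1, 1] == 1.0


class TestDescribe:
    def test_reports_classification_ratios(self, small_classification, small_fps):
        d = describe(small_classification, small_fps)
        # a1: 2 actives, 2 inactives; a2: 2 actives, 1 inactive
        assert np.isclose(d["active_inactive_ratio"]["a1"], 1.0)
        assert np.isclose(d["active_inactive_ratio"]["a2"], 2.0)

    def test_alignment_failure_raises(self, small_regression):
        fps = FingerprintSet(np.ones((2, 4), dtype=np.uint8), ["c1", "zz"])
        with pytest.raises(ValueError, match="missing compound"):
            describe(small_regression, fps)
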