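"""Cleaning, imputation, normalization, selection and intersection rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survfuse import (
    ValidationError,
    discretize_expression,
    drop_constant_features,
    drop_high_missing_features,
    impute_weighted_knn,
    intersect_cohort,
    minmax_normalize,
    select_top_variance,
)

from .conftest import make_matrix


class TestDropHighMissing:
    def test_strictly_above_threshold_dropped(self):
        vals = np.random.default_rng(0).normal(size=(100, 3))
        vals[:11, 0] = np.nan  # 11% missing -> dropped
        vals[:10, 1] = np.nan  # exactly 10% -> kept (strict comparison)
        m, dropped = drop_high_missing_features(make_matrix(vals), threshold=0.10)
        assert dropped == ["f0"]
        assert list(m.feature_ids) == ["f1", "f2"]

    def test_no_missing_is_identity(self):
        m0 = make_matrix(np.arange(12.0).reshape(4, 3))
        m, dropped = drop_high_missing_features(m0)
        assert dropped == [] and np.array_equal(m.values, m0.values)

    def test_all_dropped_is_error(self):
        vals = np.full((10, 2), np.nan)
        with pytest.raises(ValidationError, match="threshold"):
            drop_high_missing_features(make_matrix(vals), threshold=0.10)


class TestWeightedKnnImpute:
    def test_no_missing_identity(self):
        m0 = make_matrix(np.arange(20.0).reshape(5, 4))
        assert np.array_equal(impute_weighted_knn(m0).values, m0.values)

    def test_equidistant_neighbors_average(self):
        # patient 0 misses f0; patients 1 and 2 are equidistant from it on
        # the observed features and carry f0 values 2 and 4 -> impute 3
        vals = np.array(
            [
                [np.nan, 0.0, 0.0],
                [2.0, 1.0, 0.0],
                [4.0, -1.0, 0.0],
            ]
        )
        out = impute_weighted_knn(make_matrix(vals), k=2)
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_k1_copies_nearest_neighbor(self):
        vals = np.array(
            [
                [np.nan, 0.0, 0.1],
                [7.0, 0.0, 0.0],
                [100.0, 50.0, 50.0],
            ]
        )
        out = impute_weighted_knn(make_matrix(vals), k=1)
        assert out.values[0, 0] == pytest.approx(7.0)

    def test_observed_cells_bit_exact(self, rng):
        vals = rng.normal(size=(30, 6))
        mask = rng.random(vals.shape) < 0.08
        vals_nan = vals.copy()
        vals_nan[mask] = np.nan
        out = impute_weighted_knn(make_matrix(vals_nan), k=5)
        assert np.array_equal(out.values[~mask], vals[~mask])
        assert not np.isnan(out.values).any()

    def test_all_missing_patient_named(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValidationError, match="P000"):
            impute_weighted_knn(make_matrix(vals))


class TestMinmax:
    def test_linear_map(self):
        assert minmax_normalize(np.array([30.0, 50.0, 70.0])) == pytest.approx([0, 0.5, 1])

    def test_unit_range_identity(self):
        assert minmax_normalize(np.array([0.0, 1.0])) == pytest.approx([0, 1])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30).filter(lambda v: max(v) > min(v)))
    def test_output_spans_unit_interval(self, column):
        out = minmax_normalize(np.array(column))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_column_error(self):
        with pytest.raises(ValidationError, match="constant"):
            minmax_normalize(np.full(5, 3.0))


class TestDiscretize:
    def test_constant_gene_all_baseline(self):
        m = make_matrix(np.column_stack([np.full(10, 5.0), np.arange(10.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = discretize_expression(m)
        assert (out.values[:, 0] == 0).all()

    def test_extreme_outlier_flagged_over_expressed(self):
        col = np.zeros(50)
        col[0] = 50.0  # z approximately 7 after standardization
        noise = np.linspace(-0.1, 0.1, 50)
        out = discretize_expression(make_matrix((col + noise)[:, None]))
        assert out.values[0, 0] == 1.0
        assert (out.values[1:, 0] == 0).sum() >= 45

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_domain_always_ternary(self, seed):
        vals = np.random.default_rng(seed).normal(size=(20, 5)) * 10
        out = discretize_expression(make_matrix(vals))
        assert np.isin(out.values, (-1.0, 0.0, 1.0)).all()


class TestDropConstantAndTopVariance:
    def test_all_zero_column_removed(self):
        vals = np.column_stack([np.zeros(5), np.arange(5.0)])
        out = drop_constant_features(make_matrix(vals))
        assert list(out.feature_ids) == ["f1"]

    def test_no_constant_identity(self):
        m0 = make_matrix(np.random.default_rng(1).normal(size=(6, 4)))
        assert np.array_equal(drop_constant_features(m0).values, m0.values)

    def test_single_constant_feature_errors(self):
        with pytest.raises(ValidationError, match="constant"):
            drop_constant_features(make_matrix(np.ones((5, 1))))

    def test_few_features_identity_fraction_one(self):
        m0 = make_matrix(np.random.default_rng(2).normal(size=(10, 3)))
        out, frac = select_top_variance(m0, k=500)
        assert np.array_equal(out.values, m0.values) and frac == pytest.approx(1.0)

    def test_hand_computed_fraction(self):
        rng = np.random.default_rng(3)
        # build columns with population variances exactly 4, 1, 0.01
        base = rng.normal(size=12)
        base = (base - base.mean()) / base.std()
        vals = np.column_stack([2.0 * base, 1.0 * base, 0.1 * base])
        out, frac = select_top_variance(make_matrix(vals), k=2)
        assert list(out.feature_ids) == ["f0", "f1"]
        assert frac == pytest.approx(5.0 / 5.01)

    def test_low_capture_warns(self):
        base = np.random.default_rng(4).normal(size=(20, 1))
        vals = np.hstack([base, base + 0.01 * np.random.default_rng(5).normal(size=(20, 3))])
        with pytest.warns(UserWarning, match="capture"):
            select_top_variance(make_matrix(vals), k=1)

    def test_selection_invariant_to_feature_order(self, rng):
        vals = rng.normal(size=(30, 10)) * rng.uniform(0.1, 5, size=10)
        m = make_matrix(vals)
        perm = rng.permutation(10)
        m_perm = make_matrix(vals[:, perm], feature_ids=[f"f{j}" for j in perm])
        sel, _ = select_top_variance(m, k=4)
        sel_perm, _ = select_top_variance(m_perm, k=4)
        assert set(sel.feature_ids) == set(sel_perm.feature_ids)

    def test_fraction_matches_independent_recount(self, rng):
        vals = rng.normal(size=(40, 12)) * rng.uniform(0.1, 3, size=12)
        m = make_matrix(vals)
        out, frac = select_top_variance(m, k=5)
        recomputed = out.values.var(axis=0).sum() / m.values.var(axis=0).sum()
        assert frac == pytest.approx(recomputed, abs=1e-12)


class TestIntersectCohort:
    def test_single_matrix_sorted_ids(self):
        m = make_matrix(np.eye(3), patient_ids=["C", "A", "B"])
        index, aligned = intersect_cohort([m])
        assert list(index.patient_ids) == ["A", "B", "C"]
        assert list(aligned[0].patient_ids) == ["A", "B", "C"]

    def test_two_way_overlap(self):
        m1 = make_matrix(np.arange(6.0).reshape(3, 2), patient_ids=["A", "B", "C"])
        m2 = make_matrix(np.arange(6.0).reshape(3, 2), patient_ids=["B", "C", "D"])
        index, (a1, a2) = intersect_cohort([m1, m2])
        assert list(index.patient_ids) == ["B", "C"]
        assert a1.values.shape == (2, 2) and list(a2.patient_ids) == ["B", "C"]

    def test_three_way_known_overlap(self, rng):
        ids = [f"P{i}" for i in range(20)]
        shared = ids[:7]
        mats = []
        for extra in (ids[7:12], ids[12:16], ids[16:]):
            sel = shared + extra
            mats.append(make_matrix(rng.normal(size=(len(sel), 2)), patient_ids=sel))
        index, _ = intersect_cohort(mats)
        assert len(index) == 7 and set(index.patient_ids) == set(shared)

    def test_empty_intersection_errors(self):
        m1 = make_matrix(np.eye(2), patient_ids=["A", "B"])
        m2 = make_matrix(np.eye(2), patient_ids=["C", "D"])
        with pytest.raises(ValidationError, match="empty"):
            intersect_cohort([m1, m2])

    def test_idempotent_and_order_independent(self, rng):
        m1 = make_matrix(rng.normal(size=(4, 2)), patient_ids=["A", "B", "C", "D"])
        m2 = make_matrix(rng.normal(size=(3, 2)), patient_ids=["B", "D", "E"])
        i12, _ = intersect_cohort([m1, m2])
        i21, _ = intersect_cohort([m2, m1])
        assert list(i12.patient_ids) == list(i21.patient_ids)
        again, _ = intersect_cohort([m1.subset_patients(i12.patient_ids)])
        assert list(again.patient_ids) == list(i12.patient_ids)
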