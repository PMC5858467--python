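"""Stratified folds, Gaussian bootstrap, combinatorial expansion."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import neuroad as na
from neuroad.augmentation import _truncated_normal_open
from neuroad.preprocessing import FeatureMatrix


def make_matrix(arr, prefix="x"):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    n, k = arr.shape
    values = pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(k)])
    meta = pd.DataFrame(
        {"subject_id": "S01", "ad_id": [f"car_{i}" for i in range(n)], "category": "car"}
    )
    return FeatureMatrix(values, meta)


def targets_with(n, n_ones, seed=0):
    y = np.zeros(n, dtype=int)
    y[:n_ones] = 1
    return np.random.default_rng(seed).permutation(y)


class TestStratifiedTenfold:
    def test_listing_arithmetic_n100(self):
        y = targets_with(100, 30)
        folds = na.stratified_tenfold(y, seed=0)
        counts = folds.counts(y)
        assert (counts.loc[counts["fold"] <= 9, "ones"] == 3).all()
        assert (counts.loc[counts["fold"] <= 9, "zeros"] == 7).all()
        assert counts.loc[counts["fold"] == 10, "ones"].item() == 3
        assert counts.loc[counts["fold"] == 10, "zeros"].item() == 7

    def test_partitions_in_sample_size(self):
        y = targets_with(435, 200)
        folds = na.stratified_tenfold(y, seed=1)
        assert len(folds.fold_of) == 435
        assert sorted(np.unique(folds.fold_of)) == list(range(1, 11))
        # disjoint and exhaustive by construction of fold_of; check coverage
        assert sum(len(folds.indices(f)) for f in range(1, 11)) == 435

    def test_seed_changes_membership_not_counts(self):
        y = targets_with(120, 40)
        f1, f2 = na.stratified_tenfold(y, seed=1), na.stratified_tenfold(y, seed=2)
        assert f1.counts(y).equals(f2.counts(y))
        assert not np.array_equal(f1.fold_of, f2.fold_of)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            na.stratified_tenfold(np.ones(20, dtype=int), seed=0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            na.stratified_tenfold(np.array([0, 1, 0, 1]), seed=0)

    @given(st.integers(20, 500), st.floats(0.1, 0.9))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_fold_invariants_property(self, n, ratio):
        n_ones = min(n - 1, max(1, round(ratio * n)))
        y = targets_with(n, n_ones, seed=n)
        folds = na.stratified_tenfold(y, seed=n)
        counts = folds.counts(y)
        assert counts["ones"].sum() == n_ones
        assert counts["zeros"].sum() == n - n_ones
        ones, zeros = folds.ones_per_fold, folds.zeros_per_fold
        assert ones == (n_ones + 5) // 10
        for i in range(1, 10):
            row = counts[counts["fold"] == i].iloc[0]
            assert row["ones"] == max(0, min(ones, n_ones - (i - 1) * ones))
            assert row["zeros"] == max(0, min(zeros, (n - n_ones) - (i - 1) * zeros))


class TestGaussianBootstrap:
    def test_bound_forced_by_truncation(self):
        X = make_matrix(np.array([[2.0], [10.0], [4.0], [9.0]]))
        spec = na.BootstrapSpec(seed=0)
        out = na.gaussian_bootstrap_columns(X, spec)
        delta = out.values.to_numpy() - X.values.to_numpy()
        assert (np.abs(delta) < 6.0).all()

    def test_zero_scale_column_passes_through(self):
        X = make_matrix(np.column_stack([np.zeros(10), np.arange(10.0)]))
        out = na.gaussian_bootstrap_columns(X, na.BootstrapSpec(seed=1))
        np.testing.assert_array_equal(out.values["x0"], np.zeros(10))
        assert not np.array_equal(out.values["x1"], np.arange(10.0))

    def test_symmetric_min_max_column_passes_through(self):
        X = make_matrix(np.array([[-5.0], [5.0], [0.0]]))
        out = na.gaussian_bootstrap_columns(X, na.BootstrapSpec(seed=2))
        np.testing.assert_array_equal(out.values.to_numpy(), X.values.to_numpy())

    def test_scaled_perturbation_mean_matches_oracle(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 100, 10_000)
        col[0], col[1] = 0.0, 100.0  # pin min/max -> scale = 50
        X = make_matrix(col[:, None])
        out = na.gaussian_bootstrap_columns(X, na.BootstrapSpec(seed=3))
        g = (out.values.to_numpy().ravel() - col) / 50.0
        assert abs(g.mean()) < 0.05  # truncated normal is zero-mean
        assert (np.abs(g) < 1.0).all()

    def test_deterministic_under_seed(self):
        X = make_matrix(np.random.default_rng(1).uniform(0, 10, (50, 3)))
        a = na.gaussian_bootstrap_columns(X, na.BootstrapSpec(seed=7))
        b = na.gaussian_bootstrap_columns(X, na.BootstrapSpec(seed=7))
        assert a.values.equals(b.values)

    def test_rejection_sampler_stays_in_open_interval(self):
        draws = _truncated_normal_open(np.random.default_rng(5), 50_000)
        assert draws.min() > -1.0 and draws.max() < 1.0


class TestCombinatorialExpand:
    def _pair(self, n=6, k=4, seed=0):
        rng = np.random.default_rng(seed)
        X = make_matrix(rng.uniform(0, 10, (n, k)))
        boot = na.gaussian_bootstrap_columns(X, na.BootstrapSpec(seed=seed))
        return X, boot

    def test_single_column_subsets(self):
        rng = np.random.default_rng(2)
        X = make_matrix(rng.uniform(0, 10, (5, 11)))
        boot = na.gaussian_bootstrap_columns(X, na.BootstrapSpec(seed=2))
        spec = na.BootstrapSpec(seed=2, r_range=(1,), max_copies_per_r=1000,
                                expansion_cap=10**9)
        out = na.combinatorial_expand(X, boot, spec)
        assert len(out) == 12 * 5  # original + C(11,1) copies

    def test_full_enumeration_is_powerset(self):
        X, boot = self._pair(n=4, k=4)
        spec = na.BootstrapSpec(seed=0, r_range=(1, 2, 3, 4), max_copies_per_r=1000,
                                expansion_cap=10**9)
        out = na.combinatorial_expand(X, boot, spec)
        assert len(out) == 4 * (1 + 2**4 - 1)

    def test_identity_bootstrap_gives_identical_copies(self):
        X, _ = self._pair()
        spec = na.BootstrapSpec(seed=0, r_range=(1, 2), max_copies_per_r=1000,
                                expansion_cap=10**9)
        out = na.combinatorial_expand(X, X, spec)
        orig = X.values.to_numpy()
        arr = out.values.to_numpy()
        for block in range(len(out) // len(X)):
            np.testing.assert_array_equal(arr[block * len(X) : (block + 1) * len(X)], orig)

    def test_shape_mismatch_rejected(self):
        X, boot = self._pair()
        other = make_matrix(np.zeros((6, 3)))
        with pytest.raises(ValueError, match="shape"):
            na.combinatorial_expand(X, other, na.BootstrapSpec(seed=0))

    def test_provenance_tags(self):
        X, boot = self._pair()
        spec = na.BootstrapSpec(seed=0, r_range=(1,), max_copies_per_r=2,
                                expansion_cap=10**9)
        out = na.combinatorial_expand(X, boot, spec)
        tags = out.meta["provenance"].unique().tolist()
        assert tags[0] == "original"
        assert all(t.startswith("boot:r=1:cols=") for t in tags[1:])

    def test_row_ceiling_truncates_whole_copies(self):
        X, boot = self._pair(n=10, k=4)
        spec = na.BootstrapSpec(seed=0, r_range=(1, 2, 3, 4), max_copies_per_r=1000,
                                expansion_cap=35)
        out = na.combinatorial_expand(X, boot, spec)
        assert len(out) == 10 * (1 + 35 // 10)

    def test_count_matches_closed_form(self):
        for k, r_range, cap in [(5, (1, 2), 3), (6, (1, 2, 3), 100), (11, tuple(range(1, 12)), 20)]:
            X, boot = self._pair(n=3, k=k)
            spec = na.BootstrapSpec(seed=1, r_range=r_range, max_copies_per_r=cap,
                                    expansion_cap=10**9)
            out = na.combinatorial_expand(X, boot, spec)
            expected = sum(min(comb(k, r), cap) for r in r_range)
            assert len(out) == 3 * (1 + expected)
            assert na.expansion_copy_count(k, spec) == expected

    def test_deterministic_under_seed(self):
        X, boot = self._pair(n=4, k=6)
        spec = na.BootstrapSpec(seed=9, r_range=(2, 3), max_copies_per_r=4,
                                expansion_cap=10**9)
        a = na.combinatorial_expand(X, boot, spec)
        b = na.combinatorial_expand(X, boot, spec)
        assert a.values.equals(b.values)
        assert a.meta.equals(b.meta)


class TestDuplicateLabels:
    def test_arithmetic(self):
        y = targets_with(391, 130)
        assert len(na.duplicate_labels(y, 11)) == 4692

    def test_zero_copies_identity(self):
        y = targets_with(20, 5)
        np.testing.assert_array_equal(na.duplicate_labels(y, 0), y)

    def test_class_ratio_preserved(self):
        y = targets_with(50, 20)
        dup = na.duplicate_labels(y, 7)
        assert dup.mean() == y.mean()
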