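"""Compositional log-ratio ordination and permutation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kna.ensemble_stats import (
    correspondence_analysis,
    dispersion_test,
    logratio_transform,
    mean_difference_test,
    ordinate,
)


class TestCLR:
    def test_equal_frequencies_give_zero_row(self):
        clr = logratio_transform(np.full((1, 4), 0.25))
        np.testing.assert_allclose(clr, 0.0, atol=1e-12)

    def test_hand_computed_antisymmetric_table(self):
        clr_rows = np.log(np.array([[1, 3], [3, 1]]) / 4.0)
        clr_rows = clr_rows - clr_rows.mean(axis=1, keepdims=True)
        expected = clr_rows - clr_rows.mean(axis=0)
        np.testing.assert_allclose(
            logratio_transform(np.array([[1, 3], [3, 1]]) / 4.0), expected
        )
        # antisymmetric pattern, magnitude log sqrt(3)
        np.testing.assert_allclose(
            logratio_transform(np.array([[1, 3], [3, 1]]) / 4.0)[0],
            [-np.log(np.sqrt(3)), np.log(np.sqrt(3))],
        )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(0.01, 100.0))
    def test_row_scaling_invariance(self, c):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 1.0, size=(5, 6))
        scaled = x.copy()
        scaled[2] *= c
        np.testing.assert_allclose(
            logratio_transform(x), logratio_transform(scaled), atol=1e-10
        )

    def test_strict_policy_names_zero_cells(self):
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            logratio_transform(np.array([[1.0, 2.0], [1.0, 0.0]]), policy="strict")

    def test_pseudocount_handles_zeros(self):
        clr = logratio_transform(np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert np.isfinite(clr).all()


class TestOrdinate:
    def _toy(self, shifts, n_per=6, n_parts=5, spread=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for cname, shift in shifts.items():
            base = np.asarray(shift, float)
            rows.append(base + rng.normal(0, spread, size=(n_per, n_parts)))
            labels += [cname] * n_per
        return np.vstack(rows) - np.vstack(rows).mean(axis=0), np.array(labels)

    def test_scores_are_mean_centred(self):
        x, labels = self._toy({"a": np.zeros(5), "b": np.ones(5)})
        res = ordinate(x, labels)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-10
        assert np.abs(res.bca_scores.mean(axis=0)).max() < 1e-10

    def test_identical_condition_means_give_zero_between_variance(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(size=(6, 4))
        x = np.vstack([noise, noise])  # both conditions identical
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = ordinate(x - x.mean(axis=0), labels)
        assert res.bca_variance.max() < 1e-20

    def test_recovers_planted_mean_geometry(self):
        """Three conditions with mean shifts spanning a 2-D plane: BCA
        axes recover the separation (high between-condition variance and
        cluster ordering along axis 1)."""
        shifts = {
            "a": np.array([0.0, 0, 0, 0, 0]),
            "b": np.array([2.0, 0, 0, 0, 0]),
            "c": np.array([0.0, 2.0, 0, 0, 0]),
        }
        x, labels = self._toy(shifts, spread=0.05)
        res = ordinate(x, labels)
        assert res.between_variance_fraction > 0.95
        # condition means in BCA space are well separated pairwise
        means = {c: res.bca_scores[labels == c].mean(axis=0) for c in "abc"}
        for u in "abc":
            for v in "abc":
                if u < v:
                    assert np.linalg.norm(means[u] - means[v]) > 1.0

    def test_single_image_condition_rejected(self):
        x = np.zeros((3, 4))
        with pytest.raises(ValueError, match="single image"):
            ordinate(x, np.array(["a", "a", "b"]))

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match="two conditions"):
            ordinate(np.zeros((4, 3)), np.array(["a"] * 4))


class TestCorrespondenceAnalysis:
    def test_independent_table_has_zero_inertia(self):
        x = np.outer([0.3, 0.7], [0.2, 0.8])
        rows, cols, share = correspondence_analysis(x)
        assert np.abs(rows).max() < 1e-10

    def test_separates_contrasting_rows(self):
        x = np.array([[10, 1, 1], [10, 1, 1], [1, 1, 10], [1, 1, 10]], float)
        rows, _, share = correspondence_analysis(x, n_components=1)
        assert np.sign(rows[0, 0]) == np.sign(rows[1, 0])
        assert np.sign(rows[0, 0]) != np.sign(rows[2, 0])
        assert share[0] > 0.9

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            correspondence_analysis(np.array([[1.0, -1.0]]))


class TestPermutationTests:
    def test_p_value_identity_and_determinism(self, rng):
        x = rng.normal(size=(16, 2))
        labels = np.repeat(["a", "b"], 8)
        res = dispersion_test(x, labels, n_perm=199, seed=5, keep_null=True)
        expected = (1 + np.sum(res.null_distribution >= res.statistic)) / 200
        assert res.p_value == pytest.approx(expected)
        res2 = dispersion_test(x, labels, n_perm=199, seed=5)
        assert res2.p_value == res.p_value

    def test_dispersion_detects_spread_difference(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(20):
            a = rng.normal(0, 1, size=(20, 2))
            b = rng.normal(0, 3, size=(20, 2))
            x = np.vstack([a, b])
            labels = np.repeat(["a", "b"], 20)
            res = dispersion_test(x, labels, n_perm=199, seed=1)
            hits += res.p_value < 0.05
        assert hits >= 16  # >= 80% power at a 3x spread ratio

    def test_mean_difference_detects_shift(self):
        rng = np.random.default_rng(43)
        hits = 0
        for _ in range(20):
            a = rng.normal(0, 1, size=(12, 2))
            b = rng.normal(0, 1, size=(12, 2))
            b[:, 0] += 2.0  # two pooled SDs
            res = mean_difference_test(
                np.vstack([a, b]), np.repeat(["a", "b"], 12), n_perm=199, seed=1
            )
            hits += res.p_value < 0.05
        assert hits >= 18  # >= 90% power

    def test_random_relabel_of_one_condition_gives_high_p(self):
        rng = np.random.default_rng(44)
        ps = []
        for i in range(20):
            x = rng.normal(size=(24, 2))
            labels = rng.permutation(np.repeat(["a", "b"], 12))
            ps.append(mean_difference_test(x, labels, n_perm=199, seed=i).p_value)
        assert np.median(ps) > 0.3

    def test_small_n_perm_warns(self, rng):
        x = rng.normal(size=(8, 2))
        with pytest.warns(UserWarning, match="n_perm"):
            dispersion_test(x, np.repeat(["a", "b"], 4), n_perm=49, seed=0)

    def test_identical_data_statistic_within_null_range(self, rng):
        x = np.tile(rng.normal(size=(4, 2)), (2, 1))
        labels = np.repeat(["a", "b"], 4)
        res = mean_difference_test(x, labels, n_perm=99, seed=0, keep_null=True)
        assert res.null_distribution.min() <= res.statistic <= res.null_distribution.max()
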