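import numpy as np
import pytest

from pforge.response import (
    LuminescenceSeries,
    cluster_responses,
    compute_ec200,
    response_variables,
    standardize_timegrid,
    tertile_labels,
    variant_significance,
)


def _series(vid, t, dnt, ctrl, rep=0):
    return LuminescenceSeries(vid, np.array(t), np.array(dnt), np.array(ctrl), rep)


class TestStandardizeTimegrid:
    def test_identity_on_grid(self):
        s = _series("v", [0, 1, 2], [10, 20, 30], [0, 0, 0])
        out = standardize_timegrid([s], np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(out.loc[("v", 0)].to_numpy(), [10, 20, 30])

    def test_linear_interpolation(self):
        s = _series("v", [0, 2], [0, 10], [0, 0])
        out = standardize_timegrid([s], np.array([1.0]))
        assert out.loc[("v", 0)].iloc[0] == pytest.approx(5.0)

    def test_boundary_held_constant(self):
        s = _series("v", [1, 2], [5, 9], [0, 0])
        out = standardize_timegrid([s], np.array([0.0, 3.0]))
        np.testing.assert_allclose(out.loc[("v", 0)].to_numpy(), [5, 9])

    def test_single_point_rejected(self):
        s = _series("v", [1], [5], [0])
        with pytest.raises(ValueError):
            standardize_timegrid([s], np.array([0.0, 1.0]))


class TestResponseVariables:
    def test_worked_example(self):
        rv = response_variables(np.array([0, 1, 3, 2.0]), np.array([0, 1, 2, 3.0]))
        assert rv.max_diff == 3.0
        assert rv.avg_diff == pytest.approx(1.5)
        assert rv.max_slope == pytest.approx(2.0)
        assert rv.time_to_max == 2.0

    def test_constant_curve(self):
        rv = response_variables(np.full(5, 4.0), np.arange(5.0))
        assert rv.max_diff == rv.avg_diff == 4.0
        assert rv.max_slope == 0.0
        assert rv.time_to_max == 0.0

    def test_scaling_homogeneity(self, rng):
        d = rng.normal(size=8)
        t = np.arange(8.0)
        rv1 = response_variables(d, t)
        rv10 = response_variables(10 * d, t)
        assert rv10.max_diff == pytest.approx(10 * rv1.max_diff)
        assert rv10.avg_diff == pytest.approx(10 * rv1.avg_diff)
        assert rv10.max_slope == pytest.approx(10 * rv1.max_slope)
        assert rv10.time_to_max == rv1.time_to_max


class TestClusterResponses:
    def _two_groups(self, rng, n=30):
        t = np.linspace(0, 10, 12)
        a = np.sin(t / 3)
        b = np.exp(-t / 4)
        rows = []
        for i in range(n):
            base = a if i % 2 == 0 else b
            rows.append(base * rng.uniform(0.5, 5.0) + rng.normal(0, 0.01, t.size))
        return np.array(rows)

    def test_two_scaled_groups_recovered(self, rng):
        X = self._two_groups(rng)
        labels, K, diag = cluster_responses(X, k_candidates=(2, 3, 4), seed=0)
        assert K == 2
        true = np.arange(30) % 2
        agreement = max((labels == true).mean(), (labels != true).mean())
        assert agreement == 1.0

    def test_affine_rescaling_invariance(self, rng):
        X = self._two_groups(rng)
        labels1, _, _ = cluster_responses(X, k_candidates=(2, 3), seed=0)
        scale = rng.uniform(1, 10, size=(X.shape[0], 1))
        shift = rng.uniform(-5, 5, size=(X.shape[0], 1))
        labels2, _, _ = cluster_responses(X * scale + shift, k_candidates=(2, 3), seed=0)
        agreement = max((labels1 == labels2).mean(), (labels1 != labels2).mean())
        assert agreement == 1.0

    def test_seed_determinism(self, rng):
        X = self._two_groups(rng)
        l1, k1, _ = cluster_responses(X, seed=4)
        l2, k2, _ = cluster_responses(X, seed=4)
        assert k1 == k2 and (l1 == l2).all()


class TestTertileLabels:
    def test_balanced_classes(self, rng):
        y = rng.normal(size=90)
        labels = tertile_labels(y, control_value=0.0)
        counts = np.bincount(labels, minlength=3)
        assert counts.max() - counts.min() <= 1

    def test_degenerate_ties_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            tertile_labels(np.zeros(30), control_value=0.0)


class TestVariantSignificance:
    def test_null_calibration(self, rng):
        reps = {f"v{i}": rng.normal(0, 1, 4) for i in range(200)}
        control = rng.normal(0, 1, 4)
        df, fdr = variant_significance(reps, control, n_random=20, rng=rng)
        assert (df["p"] <= 0.05).mean() < 0.15

    def test_large_shift_detected(self, rng):
        reps = {"shifted": np.array([10.0, 10.1, 9.9, 10.05])}
        control = np.array([0.0, 0.05, -0.05, 0.02])
        df, _ = variant_significance(reps, control, n_random=5, rng=rng)
        assert df.loc[0, "p"] < 0.001

    def test_fdr_is_null_over_observed_ratio(self, rng):
        # half the variants strongly shifted: FDR should be well below 1
        reps = {f"s{i}": rng.normal(8, 0.1, 3) for i in range(20)}
        reps.update({f"n{i}": rng.normal(0, 0.1, 3) for i in range(20)})
        control = rng.normal(0, 0.1, 3)
        df, fdr = variant_significance(reps, control, n_random=20, rng=rng)
        assert 0 <= fdr < 1


class TestEC200:
    def test_exact_hit_returns_dose(self):
        assert compute_ec200([0.1, 0.5, 1.0], [1.2, 2.0, 3.5]) == pytest.approx(0.5)

    def test_log_linear_interpolation(self):
        # hand value: 10 ** (-1 + (ln2 - ln1.5) / (ln3 - ln1.5))
        expected = 10 ** (-1 + (np.log(2) - np.log(1.5)) / (np.log(3) - np.log(1.5)))
        assert compute_ec200([0.1, 1.0], [1.5, 3.0]) == pytest.approx(expected)
        assert compute_ec200([0.1, 1.0], [1.5, 3.0]) == pytest.approx(0.26, abs=0.005)

    def test_never_reached_sentinel(self):
        assert compute_ec200([0.1, 1.0, 10.0], [1.1, 1.4, 1.9]) is None

    def test_non_monotone_uses_first_crossing(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pforge"):
            value = compute_ec200([0.1, 1.0, 10.0], [1.0, 2.5, 1.5])
        assert 0.1 < value < 1.0
        assert any("first crossing" in r.message for r in caplog.records)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compute_ec200([0.1], [2.0])
        with pytest.raises(ValueError):
            compute_ec200([0.1, 1.0], [-1.0, 2.0])
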