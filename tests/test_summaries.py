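"""Summary statistics, weighted distances, adaptation, inverse regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellabc.lattice import Trajectory
from cellabc.problem import SummaryStatisticSpec
from cellabc.summaries import (
    DistanceSpec,
    StatisticVector,
    adapt_weights,
    compute_summaries,
    distance,
    fit_regression_statistics,
)


def make_traj(infected, dead=None, snapshots=None, n_sites=49):
    infected = np.asarray(infected, dtype=float)
    dead = np.zeros_like(infected) if dead is None else np.asarray(dead, dtype=float)
    times = np.arange(len(infected), dtype=float)
    return Trajectory(
        times=times,
        series={
            "infected_count": infected,
            "dead_count": dead,
            "susceptible_count": n_sites - infected - dead,
        },
        snapshots=snapshots or {},
        n_sites=n_sites,
    )


class TestRegistry:
    def test_count_timeseries_zero_trajectory(self):
        traj = make_traj([0, 0, 0])
        spec = SummaryStatisticSpec(
            "s", "count_timeseries", {"observable": "infected_count", "times": [0, 1, 2]}, []
        )
        out = compute_summaries(traj, [spec])
        np.testing.assert_array_equal(out.values, [0, 0, 0])
        assert out.names == ["s[0]", "s[1]", "s[2]"]

    def test_patch_radius_of_single_site(self):
        traj = make_traj([1])
        spec = SummaryStatisticSpec("r", "patch_radius_timeseries", {"times": [0]}, [])
        out = compute_summaries(traj, [spec])
        assert out.values[0] == pytest.approx(np.sqrt(1 / np.pi))

    def test_radial_profile_matches_hand_count(self):
        # 7x7 indicator: center site plus the four cells at distance 3 on the
        # axes. Two equal radial bins split [0, sqrt(18)] at ~2.12; squared
        # lattice distances <= 4.5 (i.e. 0, 1, 2, 4) fall in the inner bin:
        # 1 + 4 + 4 + 4 = 13 sites, of which only the center is set -> 1/13.
        # The outer bin holds the remaining 36 sites, 4 of them set -> 1/9.
        grid = np.zeros((7, 7))
        grid[3, 3] = 1
        grid[0, 3] = grid[6, 3] = grid[3, 0] = grid[3, 6] = 1
        traj = make_traj([5], snapshots={0.0: {"infected": grid}})
        spec = SummaryStatisticSpec(
            "rp", "radial_profile", {"observable": "infected", "time": 0.0, "n_bins": 2}, []
        )
        out = compute_summaries(traj, [spec])
        np.testing.assert_allclose(out.values, [1 / 13, 1 / 9])

    def test_final_fraction(self):
        traj = make_traj([0, 7], n_sites=49)
        spec = SummaryStatisticSpec(
            "ff", "final_fraction", {"observable": "infected_count"}, []
        )
        out = compute_summaries(traj, [spec])
        assert out.values[0] == pytest.approx(7 / 49)

    def test_unknown_function_raises(self):
        with pytest.raises(KeyError, match="no_such"):
            compute_summaries(make_traj([0]), [SummaryStatisticSpec("x", "no_such", {}, [])])

    def test_missing_time_raises(self):
        spec = SummaryStatisticSpec(
            "s", "count_timeseries", {"observable": "infected_count", "times": [99]}, []
        )
        with pytest.raises(KeyError):
            compute_summaries(make_traj([0]), [spec])


class TestDistance:
    def sv(self, *vals):
        return StatisticVector(np.array(vals, dtype=float), [f"s{i}" for i in range(len(vals))])

    def test_identical_vectors_have_zero_distance(self):
        d = DistanceSpec(p=2, adapt="none")
        assert distance(self.sv(1, 2, 3), self.sv(1, 2, 3), d) == 0.0

    def test_euclidean_three_four_five(self):
        d = DistanceSpec(p=2, adapt="none")
        assert distance(self.sv(3, 4), self.sv(0, 0), d) == pytest.approx(5.0)

    def test_weighted_l1(self):
        d = DistanceSpec(p=1, weights=np.array([2.0, 0.0]), adapt="none")
        assert distance(self.sv(1, 7), self.sv(0, 0), d) == pytest.approx(2.0)

    def test_name_mismatch_raises(self):
        a = StatisticVector(np.array([1.0]), ["a"])
        b = StatisticVector(np.array([1.0]), ["b"])
        with pytest.raises(ValueError, match="mismatch"):
            distance(a, b, DistanceSpec(adapt="none"))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 2]))
    def test_pseudometric_on_random_triples(self, seed, p):
        rng = np.random.default_rng(seed)
        x, y, z = (self.sv(*rng.normal(size=4)) for _ in range(3))
        w = rng.random(4)
        d = DistanceSpec(p=p, weights=w, adapt="none")
        assert distance(x, y, d) == pytest.approx(distance(y, x, d))
        assert distance(x, z, d) <= distance(x, y, d) + distance(y, z, d) + 1e-12


class TestAdaptWeights:
    def pop(self, mat):
        mat = np.asarray(mat, dtype=float)
        names = [f"s{i}" for i in range(mat.shape[1])]
        return [StatisticVector(row, names) for row in mat]

    def test_constant_statistic_gets_zero_weight(self):
        w = adapt_weights(self.pop([[1, 0], [1, 1], [1, 2]]), "sd")
        assert w[0] == 0.0 and w[1] > 0

    def test_sd_weights_are_reciprocal_scales(self, rng):
        a = rng.normal(0, 1, size=400)
        b = rng.normal(0, 10, size=400)
        w = adapt_weights(self.pop(np.column_stack([a, b])), "sd")
        assert w[0] / w[1] == pytest.approx(np.std(b, ddof=1) / np.std(a, ddof=1))

    def test_mad_matches_brute_force(self, rng):
        mat = rng.lognormal(size=(300, 3))
        w = adapt_weights(self.pop(mat), "mad")
        for i in range(3):
            med = np.median(mat[:, i])
            mad = np.median(np.abs(mat[:, i] - med))
            assert w[i] == pytest.approx(1.0 / mad)

    @pytest.mark.parametrize("scheme", ["mad", "sd"])
    def test_scale_equivariance(self, scheme, rng):
        mat = rng.normal(size=(100, 2)) + 5
        w1 = adapt_weights(self.pop(mat), scheme)
        scaled = mat.copy()
        scaled[:, 0] *= 3.0
        w2 = adapt_weights(self.pop(scaled), scheme)
        assert w2[0] == pytest.approx(w1[0] / 3.0)
        assert w2[1] == pytest.approx(w1[1])


class TestInverseRegression:
    def test_exact_linear_relation_recovered(self, rng):
        s = rng.normal(size=(50, 3))
        theta = 2.0 * s[:, 0:1] - 1.0
        rm = fit_regression_statistics(
            list(theta), [StatisticVector(row, ["a", "b", "c"]) for row in s]
        )
        np.testing.assert_allclose(rm.B, [[2, 0, 0]], atol=1e-8)
        np.testing.assert_allclose(rm.b0, [-1], atol=1e-8)

    def test_duplicated_columns_trigger_ridge_with_stable_predictions(self, rng):
        s = rng.normal(size=(60, 2))
        s_dup = np.column_stack([s, s[:, 0]])
        theta = s[:, 0:1] * 3.0 + 0.5
        names3 = ["a", "b", "a2"]
        rm = fit_regression_statistics(
            list(theta), [StatisticVector(row, names3) for row in s_dup]
        )
        pred = np.array([rm(row) for row in s_dup])
        np.testing.assert_allclose(pred, theta, atol=1e-6)

    def test_slope_matches_analytic_ols_on_gaussian_toy(self):
        rng = np.random.default_rng(42)
        n = 500
        theta = rng.normal(size=n)
        s = theta + rng.normal(scale=0.1, size=n)
        rm = fit_regression_statistics(
            list(theta[:, None]), [StatisticVector([v], ["s"]) for v in s]
        )
        # analytic slope of theta on s: cov/var = 1/(1+0.01)
        slope_true = 1.0 / 1.01
        se = np.sqrt((0.01 / 1.01) / n) / np.sqrt(1.01)  # rough SE of OLS slope
        assert abs(rm.B[0, 0] - slope_true) < 3 * max(se, 0.01)

    def test_insufficient_samples_raise(self, rng):
        s = rng.normal(size=(3, 3))
        with pytest.raises(ValueError, match="samples"):
            fit_regression_statistics(
                list(rng.normal(size=(3, 1))),
                [StatisticVector(row, ["a", "b", "c"]) for row in s],
            )

    def test_projected_distance_invariant_to_affine_reparametrization(self, rng):
        """Rescaling raw statistics and refitting leaves projected distances unchanged."""
        s = rng.normal(size=(80, 2))
        theta = s @ np.array([[1.0], [-2.0]]) + 0.3
        names = ["a", "b"]
        A = np.array([[3.0, 0.5], [0.0, -2.0]])  # invertible affine map
        b = np.array([1.0, -4.0])
        s2 = s @ A.T + b
        rm1 = fit_regression_statistics(list(theta), [StatisticVector(r, names) for r in s])
        rm2 = fit_regression_statistics(list(theta), [StatisticVector(r, names) for r in s2])
        d1 = DistanceSpec(p=2, adapt="none", regression_map=rm1)
        d2 = DistanceSpec(p=2, adapt="none", regression_map=rm2)
        x1, y1 = StatisticVector(s[0], names), StatisticVector(s[1], names)
        x2, y2 = StatisticVector(s2[0], names), StatisticVector(s2[1], names)
        assert distance(x1, y1, d1) == pytest.approx(distance(x2, y2, d2), rel=1e-8)
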