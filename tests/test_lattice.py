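"""Physics of the lattice simulator: diffusion, infection hazards, bookkeeping."""

import numpy as np
import pytest

from cellabc.lattice import (
    DEAD,
    INFECTED,
    SUSCEPTIBLE,
    BudgetExceeded,
    LatticeState,
    Trajectory,
    ViralParams,
    diffusion_step,
    infection_probability,
    run_viral_model,
    viral_step,
)


class TestDiffusion:
    def test_uniform_field_is_invariant(self):
        f = np.full((12, 9), 3.7)
        out = diffusion_step(f, D=0.25, decay=0.0, source=np.zeros_like(f), dt=1.0)
        np.testing.assert_allclose(out, f)

    def test_mass_conserved_under_zero_flux(self, rng):
        f = rng.random((20, 31)) * 5
        total = f.sum()
        for _ in range(50):
            f = diffusion_step(f, D=0.2, decay=0.0, source=np.zeros_like(f), dt=1.0)
        assert f.sum() == pytest.approx(total, rel=1e-13)

    def test_stability_bound_enforced(self):
        f = np.zeros((5, 5))
        with pytest.raises(ValueError, match="stability"):
            diffusion_step(f, D=1.0, decay=0.0, source=f, dt=1.0)

    def test_point_mass_matches_heat_kernel(self):
        """Radial profile of a spreading point mass vs the 2-D Gaussian kernel."""
        n = 101
        f = np.zeros((n, n))
        f[n // 2, n // 2] = 1.0
        # D*dt well below the 1/4 stability bound: the one-step kernel keeps
        # weight on the center site, so no checkerboard parity artifact
        D, dt, steps = 0.2, 0.5, 200
        for _ in range(steps):
            f = diffusion_step(f, D, 0.0, np.zeros_like(f), dt)
        t = steps * dt
        yy, xx = np.mgrid[0:n, 0:n]
        r2 = (yy - n // 2) ** 2.0 + (xx - n // 2) ** 2.0
        analytic = np.exp(-r2 / (4 * D * t)) / (4 * np.pi * D * t)
        # compare radially-binned profiles inside the bulk (far from edges)
        r = np.sqrt(r2)
        mask = r < 25
        bins = np.floor(r[mask]).astype(int)
        prof_num = np.bincount(bins, weights=f[mask]) / np.bincount(bins)
        prof_ana = np.bincount(bins, weights=analytic[mask]) / np.bincount(bins)
        rms = np.sqrt(np.mean((prof_num - prof_ana) ** 2)) / prof_ana.max()
        assert rms < 0.02

    def test_nonnegative_after_many_random_steps(self, rng):
        f = rng.random((15, 15))
        params_ok = dict(D=0.2, decay=0.9, dt=1.0)
        for _ in range(1000):
            src = rng.random((15, 15)) * 0.1
            f = diffusion_step(f, params_ok["D"], params_ok["decay"], src, params_ok["dt"])
            assert (f >= 0).all()


class TestInfectionProbability:
    def test_zero_hazard(self):
        p = ViralParams(dt=1.0)
        assert infection_probability(0.0, 0, p) == 0.0

    def test_direct_substitution(self):
        p = ViralParams(beta_cf=0.0, beta_cc=0.1, dt=1.0)
        assert infection_probability(0.0, 2, p) == pytest.approx(1 - np.exp(-0.2))

    def test_monotone_and_saturating(self):
        p = ViralParams(beta_cf=1.0, beta_cc=1.0, dt=1.0)
        vals = [infection_probability(v, n, p) for v, n in [(0, 0), (1, 0), (1, 1), (5, 3)]]
        assert vals == sorted(vals)
        assert infection_probability(1e9, 4, p) == pytest.approx(1.0)


class TestViralStep:
    def test_no_infection_without_infected(self, rng):
        state = LatticeState(np.zeros((9, 9), dtype=np.uint8), np.zeros((9, 9)))
        out = viral_step(state, ViralParams(), rng)
        assert (out.cell_state == SUSCEPTIBLE).all()
        assert (out.virion_field == 0).all()

    def test_zero_rates_freeze_infection_count(self, rng):
        params = ViralParams(beta_cf=0.0, beta_cc=0.0)
        state = LatticeState.center_infected(15, 15)
        n0 = (state.cell_state == INFECTED).sum() + (state.cell_state == DEAD).sum()
        for _ in range(50):
            state = viral_step(state, params, rng)
            n = (state.cell_state == INFECTED).sum() + (state.cell_state == DEAD).sum()
            assert n == n0

    def test_single_step_infections_match_binomial_oracle(self):
        """Cell-to-cell route only: new infections ~ Binomial(4, 1-e^{-beta_cc dt})."""
        params = ViralParams(beta_cf=0.0, beta_cc=0.2, p_prod=0.0, D=0.0, delta_death=0.0, dt=1.0)
        p_hit = 1 - np.exp(-params.beta_cc * params.dt)
        n_rep = 10_000
        rng = np.random.default_rng(7)
        init = LatticeState.center_infected(21, 21)
        new_counts = np.empty(n_rep)
        for r in range(n_rep):
            out = viral_step(init, params, rng)
            new_counts[r] = (out.cell_state == INFECTED).sum() - 1
        mean, se = 4 * p_hit, np.sqrt(4 * p_hit * (1 - p_hit) / n_rep)
        assert abs(new_counts.mean() - mean) < 3 * se

    def test_cell_count_conservation(self, rng):
        state = LatticeState.center_infected(20, 20)
        for _ in range(100):
            state = viral_step(state, ViralParams(), rng)
            assert sum(state.counts()) == 400

    def test_field_nonnegative_over_random_runs(self, rng):
        state = LatticeState.center_infected(12, 12)
        params = ViralParams(c_decay=1.0, dt=0.1)  # decay*dt well under 1
        for _ in range(200):
            state = viral_step(state, params, rng)
            assert (state.virion_field >= 0).all()


class TestRunViralModel:
    def test_reproducible_for_equal_seed(self):
        params = ViralParams(t_end=3.0)
        init = LatticeState.center_infected(20, 20)
        t1 = run_viral_model(params, init, 42, record_times=[0, 1, 2, 3])
        t2 = run_viral_model(params, init, 42, record_times=[0, 1, 2, 3])
        for key in t1.series:
            np.testing.assert_array_equal(t1.series[key], t2.series[key])

    def test_different_seed_differs(self):
        params = ViralParams(t_end=5.0)
        init = LatticeState.center_infected(20, 20)
        t1 = run_viral_model(params, init, 1, record_times=[5])
        t2 = run_viral_model(params, init, 2, record_times=[5])
        assert not np.array_equal(t1.series["infected_count"], t2.series["infected_count"])

    def test_zero_t_end_records_only_initial_state(self):
        params = ViralParams(t_end=0.0)
        init = LatticeState.center_infected(10, 10)
        traj = run_viral_model(params, init, 0)
        assert len(traj.times) == 1
        assert traj.series["infected_count"][0] == 1

    def test_constant_source_accumulates_exactly(self):
        """Only production active: total virions = n_steps * p_prod * dt."""
        params = ViralParams(
            beta_cf=0, beta_cc=0, p_prod=1.0, c_decay=0, D=0.25, delta_death=0, dt=0.5, t_end=5.0
        )
        init = LatticeState.center_infected(11, 11)
        traj = run_viral_model(params, init, 0, record_times=[5.0])
        assert traj.series["virion_total"][0] == pytest.approx(10 * 1.0 * 0.5, rel=1e-12)

    def test_budget_exhaustion_raises(self):
        params = ViralParams(t_end=5.0)
        init = LatticeState.center_infected(10, 10)
        with pytest.raises(BudgetExceeded):
            run_viral_model(params, init, 0, record_times=[5.0], budget=10)

    def test_nonbinding_budget_identical_to_unbounded(self):
        params = ViralParams(t_end=2.0)
        init = LatticeState.center_infected(10, 10)
        a = run_viral_model(params, init, 9, record_times=[2.0], budget=10_000)
        b = run_viral_model(params, init, 9, record_times=[2.0])
        np.testing.assert_array_equal(a.series["infected_count"], b.series["infected_count"])

    def test_extinction_freezes_counts_and_saves_work(self):
        # pure cell-to-cell spread with certain death: epidemic always dies out
        params = ViralParams(
            beta_cf=0, beta_cc=0.0, p_prod=0.0, c_decay=0, D=0, delta_death=100.0, dt=0.1, t_end=10
        )
        init = LatticeState.center_infected(10, 10)
        traj = run_viral_model(params, init, 3)
        assert traj.work < 100
        assert traj.series["infected_count"][-1] == 0
        assert traj.series["dead_count"][-1] == 1
        assert len(traj.times) == 101  # all requested records still present


def test_trajectory_at_unknown_time_raises():
    traj = Trajectory(times=np.array([0.0, 1.0]), series={"x": np.array([1.0, 2.0])})
    assert traj.at("x", 1.0) == 2.0
    with pytest.raises(KeyError):
        traj.at("x", 0.5)
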