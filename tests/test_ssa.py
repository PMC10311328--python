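"""Direct-method simulator: waiting times, grids, ensembles, escape times."""

import math

import numpy as np
import pytest
from scipy import stats

import wildmoments as wm


class TestTimeGrid:
    def test_log_grid_shape(self):
        grid = wm.TimeGrid.log(5.0)
        assert len(grid) == 1001
        assert grid.points[0] == 0.0
        assert grid.points[-1] == 5.0
        assert np.all(np.diff(grid.points) > 0)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            wm.TimeGrid.log(5.0, t_min=10.0)
        with pytest.raises(ValueError):
            wm.TimeGrid(points=np.array([0.0, 2.0, 1.0]))


class TestSimulateTrajectory:
    def test_degenerate_system_rests(self):
        dead = wm.ReactionSystem("dead", (wm.Reaction(nu=+1, kind="constant", rate=0.0),))
        traj = wm.simulate_trajectory(dead, x0=5, t_end=3.0, seed=1)
        assert traj.final_state == 5
        assert traj.draw_count == 0
        assert len(traj.event_times) == 0
        assert traj.state_at(1.5) == 5

    def test_crossing_draw_counted(self):
        """A trajectory with no committed event still records the draw that
        crossed the horizon."""
        slow = wm.ReactionSystem("slow", (wm.Reaction(nu=+1, kind="constant", rate=1e-6),))
        traj = wm.simulate_trajectory(slow, x0=1, t_end=1.0, seed=4)
        assert len(traj.event_times) == 0
        assert traj.draw_count == 1
        assert traj.final_state == 1

    def test_draw_count_is_events_plus_one_when_uncapped(self, system_P):
        for seed in range(5):
            traj = wm.simulate_trajectory(system_P, x0=1, t_end=5.0, seed=seed)
            assert not traj.capped
            assert traj.draw_count == len(traj.event_times) + 1

    def test_event_times_strictly_increasing_and_steps_valid(self, system_W):
        traj = wm.simulate_trajectory(system_W, x0=1, t_end=5.0, cap=5000, seed=12)
        assert np.all(np.diff(traj.event_times) > 0)
        steps = np.diff(np.concatenate([[traj.x0], traj.states]))
        assert set(np.unique(steps)) <= {-1, +1}

    def test_pure_growth_always_caps(self):
        growth = wm.build_system("pure_growth")
        for seed in range(10):
            traj = wm.simulate_trajectory(growth, x0=1, t_end=30.0, cap=10_000, seed=seed)
            assert traj.capped
            assert traj.draw_count == 10_000
            assert np.isfinite(traj.cap_time)

    def test_invalid_arguments(self, system_P):
        with pytest.raises(ValueError):
            wm.simulate_trajectory(system_P, x0=-1, t_end=1.0)
        with pytest.raises(ValueError):
            wm.simulate_trajectory(system_P, x0=1, t_end=0.0)

    def test_waiting_time_mean(self):
        """In a frozen-rate system the waiting times are Exp(lambda) with
        mean 1/lambda."""
        lam = 4.0
        const = wm.ReactionSystem("const", (wm.Reaction(nu=+1, kind="constant", rate=lam),))
        traj = wm.simulate_trajectory(const, x0=0, t_end=25_000.0, cap=200_000, seed=3)
        waits = np.diff(np.concatenate([[0.0], traj.event_times]))
        n = len(waits)
        assert n > 50_000
        se = waits.std(ddof=1) / math.sqrt(n)
        assert abs(waits.mean() - 1 / lam) < 3 * se


class TestEnsemble:
    def test_determinism(self, system_P):
        a = wm.run_ensemble(system_P, 1, 2.0, 100, base_seed=5)
        b = wm.run_ensemble(system_P, 1, 2.0, 100, base_seed=5)
        np.testing.assert_array_equal(a.states_on_grid, b.states_on_grid)
        np.testing.assert_array_equal(a.draw_counts, b.draw_counts)

    def test_initial_column_is_x0(self, ensemble_P):
        assert np.all(ensemble_P.states_on_grid[:, 0] == 1)

    def test_immigration_death_mean_matches_moment_ode(self, ensemble_P):
        """At t=5 the ensemble mean must agree with the closed-form solution
        of dE/dt = 10 - E from E(0)=1, i.e. 10 - 9 e^-5."""
        col = ensemble_P.column(5.0).astype(float)
        target = 10 - 9 * math.exp(-5)
        se = col.std(ddof=1) / math.sqrt(len(col))
        assert abs(col.mean() - target) < 3 * se

    def test_immigration_death_equilibrium_is_poisson(self, ensemble_P):
        """Chi-square test of the t=5 states against Poisson(10)."""
        col = ensemble_P.column(5.0)
        po = stats.poisson(10)
        cells = list(range(3, 19))  # expected count >= ~5 per cell at n=5000
        observed = np.array(
            [(col < cells[0]).sum()]
            + [(col == k).sum() for k in cells]
            + [(col > cells[-1]).sum()]
        )
        expected = np.array(
            [po.cdf(cells[0] - 1)] + [po.pmf(k) for k in cells] + [po.sf(cells[-1])]
        ) * len(col)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=len(observed) - 1) > 0.01

    def test_W_states_never_below_one(self, ensemble_W):
        """From x(0)=1, mass-action x(x-1) death cannot fire at x=1, so no
        trajectory ever drops below 1."""
        assert ensemble_W.states_on_grid.min() >= 1

    def test_W_parity(self, ensemble_W):
        """Every uncapped trajectory that finishes at x=1 made an even number
        of +-1 moves plus the crossing draw: its draw count is odd."""
        uncapped_at_1 = (~ensemble_W.capped_flags) & (ensemble_W.final_states == 1)
        assert uncapped_at_1.any()
        assert np.all(ensemble_W.draw_counts[uncapped_at_1] % 2 == 1)

    def test_grid_must_end_at_t_end(self, system_P):
        with pytest.raises(ValueError):
            wm.run_ensemble(system_P, 1, 2.0, 10, grid=wm.TimeGrid.log(5.0))

    def test_save_round_trip(self, system_P, tmp_path):
        import pandas as pd

        ens = wm.run_ensemble(system_P, 1, 1.0, 20, base_seed=2)
        ens.save(tmp_path)
        df = pd.read_csv(tmp_path / "trajectories.csv")
        np.testing.assert_array_equal(df["draw_count"].to_numpy(), ens.draw_counts)
        grid_df = pd.read_csv(tmp_path / "states_on_grid.csv")
        assert grid_df.shape == ens.states_on_grid.shape


class TestEscapeTimes:
    def test_pure_growth_escape_mean(self):
        """Escape time = sum of Exp(k^2) waits over k=1..cap; its mean is the
        partial sum of 1/k^2, computed here as the brute-force oracle."""
        growth = wm.build_system("pure_growth")
        grid = wm.TimeGrid.log(30.0)
        ens = wm.run_ensemble(growth, 1, 30.0, 500, grid=grid, cap=10_000, base_seed=17)
        et = wm.escape_times(ens)
        times = et.loc[~et["censored"], "time"].to_numpy()
        assert len(times) == 500  # horizon far beyond any realistic escape time
        oracle = sum(1.0 / k**2 for k in range(1, 10_001))
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert abs(times.mean() - oracle) < 3 * se
        assert np.all((times >= 0) & (times <= 30.0))

    def test_birth_limited_system_all_censored(self, system_P):
        ens = wm.run_ensemble(system_P, 1, 2.0, 50, cap=100_000, base_seed=1)
        et = wm.escape_times(ens)
        assert et["censored"].all()
        assert np.all(et["time"] == 2.0)

    def test_trajectory_list_source(self):
        growth = wm.build_system("pure_growth")
        trajs = [wm.simulate_trajectory(growth, 1, 30.0, cap=1000, seed=s) for s in range(5)]
        et = wm.escape_times(trajs)
        assert (~et["censored"]).all()
        assert np.allclose(et["time"], [t.cap_time for t in trajs])
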