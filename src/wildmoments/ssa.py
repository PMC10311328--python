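"""Direct-method stochastic simulation for one-species reaction networks.

Implements the classic direct method: in state ``x`` the waiting time to the
next reaction is exponential with rate ``lambda = sum_j a_j(x)`` and the
firing channel is chosen with probability ``a_j(x)/lambda``.  Each waiting
time is one *draw*; the convention used throughout is that the draw that
would carry the trajectory past ``t_end`` (and is therefore never committed)
still counts.  This makes the step count of a trajectory that starts and
ends at the same state odd -- an observable parity signature of networks
whose trajectories rest at a low-propensity state.

Simulations carry a reaction cap.  For explosive systems (quadratic birth)
a single trajectory can fire an astronomically large number of reactions in
a fraction of simulated time, so the cap is what makes ensemble runs finish;
capped trajectories are retained and flagged, never dropped.

The inner loops are compiled with numba; ensembles of thousands of capped
trajectories simulate in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .systems import ReactionSystem

__all__ = [
    "TimeGrid",
    "Trajectory",
    "Ensemble",
    "simulate_trajectory",
    "run_ensemble",
    "escape_times",
    "DEFAULT_CAP",
]

#: default reaction cap per trajectory
DEFAULT_CAP = 10_000


@dataclass(frozen=True)
class TimeGrid:
    """``{0}`` followed by logarithmically uniform points on ``[t_min, t_end]``."""

    points: np.ndarray

    @classmethod
    def log(cls, t_end: float, t_min: float = 1e-3, n_points: int = 1001) -> "TimeGrid":
        """Build the standard log grid: 0 plus ``n_points - 1`` log-uniform points."""
        if not (0 < t_min < t_end):
            raise ValueError("need 0 < t_min < t_end")
        if n_points < 2:
            raise ValueError("need at least 2 grid points")
        pts = np.concatenate([[0.0], np.geomspace(t_min, t_end, n_points - 1)])
        return cls(points=pts)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts[0] != 0.0 or np.any(np.diff(pts) <= 0):
            raise ValueError("grid must start at 0 and be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def t_end(self) -> float:
        return float(self.points[-1])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Trajectory:
    """One SSA realization: committed event times and the states after them.

    ``draw_count`` counts every waiting-time draw including the final,
    uncommitted draw that crosses ``t_end`` (when the cap was not hit).
    ``cap_time`` is the time of the cap-hitting event for capped runs, NaN
    otherwise.
    """

    event_times: np.ndarray
    states: np.ndarray
    x0: int
    t_end: float
    draw_count: int
    capped: bool
    seed: int
    cap_time: float = float("nan")

    def state_at(self, t: float) -> int:
        """State of the right-continuous step function at time ``t``."""
        if t < 0:
            raise ValueError("t must be >= 0")
        i = int(np.searchsorted(self.event_times, t, side="right"))
        return self.x0 if i == 0 else int(self.states[i - 1])

    @property
    def final_state(self) -> int:
        return self.x0 if len(self.states) == 0 else int(self.states[-1])


@dataclass
class Ensemble:
    """``n`` trajectories of one system evaluated on a shared time grid."""

    system_name: str
    grid: TimeGrid
    states_on_grid: np.ndarray  # (n, len(grid)) int64
    draw_counts: np.ndarray  # (n,) int64
    final_states: np.ndarray  # (n,) int64
    capped_flags: np.ndarray  # (n,) bool
    cap_times: np.ndarray  # (n,) float64, NaN when not capped
    base_seed: int
    cap: int

    @property
    def n(self) -> int:
        return self.states_on_grid.shape[0]

    def column(self, t: float) -> np.ndarray:
        """States of all trajectories at grid time ``t``."""
        idx = np.flatnonzero(np.isclose(self.grid.points, t, rtol=0, atol=1e-12))
        if len(idx) == 0:
            raise ValueError(f"t={t} is not a grid point")
        return self.states_on_grid[:, idx[0]]

    # --- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write grid CSV, per-trajectory summary CSV and JSON metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        grid_df = pd.DataFrame(
            self.states_on_grid, columns=[f"{t:.10g}" for t in self.grid.points]
        )
        grid_df.to_csv(directory / "states_on_grid.csv", index=False)
        summary = pd.DataFrame(
            {
                "seed": self.base_seed + np.arange(self.n),
                "draw_count": self.draw_counts,
                "final_state": self.final_states,
                "capped": self.capped_flags.astype(int),
                "cap_time": self.cap_times,
            }
        )
        summary.to_csv(directory / "trajectories.csv", index=False)
        meta = {
            "system": self.system_name,
            "n": int(self.n),
            "cap": int(self.cap),
            "base_seed": int(self.base_seed),
            "t_end": self.grid.t_end,
            "grid_points": len(self.grid),
        }
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))


# --- compiled kernels ------------------------------------------------------


@njit(cache=True)
def _total_propensity(x, nus, kinds, rates, guards, acc):
    total = 0.0
    for j in range(len(rates)):
        if x < guards[j]:
            a = 0.0
        elif kinds[j] == 0:
            a = rates[j]
        elif kinds[j] == 1:
            a = rates[j] * x
        elif kinds[j] == 2:
            a = rates[j] * x * x
        else:
            a = rates[j] * x * (x - 1)
        acc[j] = a
        total += a
    return total


@njit(cache=True)
def _sim_events(nus, kinds, rates, guards, x0, t_end, cap, seed):
    """Full event record of one trajectory.

    Returns (event_times, states, draw_count, capped, cap_time); arrays are
    truncated to the number of committed events.
    """
    np.random.seed(seed)
    times = np.empty(cap, dtype=np.float64)
    states = np.empty(cap, dtype=np.int64)
    acc = np.empty(len(rates), dtype=np.float64)
    x = x0
    t = 0.0
    n_events = 0
    draws = 0
    capped = False
    cap_time = np.nan
    while True:
        lam = _total_propensity(x, nus, kinds, rates, guards, acc)
        if not np.isfinite(lam):
            raise ValueError("non-finite total propensity")
        if lam == 0.0:
            break  # absorbing state: rest until t_end without drawing
        tau = -np.log(1.0 - np.random.random()) / lam
        if t + tau > t_end:
            draws += 1  # the crossing draw
            break
        t += tau
        draws += 1
        # pick the firing channel proportionally to its propensity
        u = np.random.random() * lam
        csum = 0.0
        j = 0
        for jj in range(len(rates)):
            csum += acc[jj]
            if u < csum:
                j = jj
                break
        x += nus[j]
        times[n_events] = t
        states[n_events] = x
        n_events += 1
        if n_events >= cap:
            capped = True
            cap_time = t
            break
    return times[:n_events], states[:n_events], draws, capped, cap_time


@njit(cache=True)
def _sim_grid(nus, kinds, rates, guards, x0, t_end, cap, seed, grid):
    """One trajectory evaluated on a time grid, without storing events."""
    np.random.seed(seed)
    out = np.empty(len(grid), dtype=np.int64)
    acc = np.empty(len(rates), dtype=np.float64)
    x = x0
    t = 0.0
    gi = 0
    n_events = 0
    draws = 0
    capped = False
    cap_time = np.nan
    while True:
        lam = _total_propensity(x, nus, kinds, rates, guards, acc)
        if not np.isfinite(lam):
            raise ValueError("non-finite total propensity")
        if lam == 0.0:
            break
        tau = -np.log(1.0 - np.random.random()) / lam
        if t + tau > t_end:
            draws += 1
            break
        t += tau
        draws += 1
        while gi < len(grid) and grid[gi] < t:
            out[gi] = x
            gi += 1
        u = np.random.random() * lam
        csum = 0.0
        j = 0
        for jj in range(len(rates)):
            csum += acc[jj]
            if u < csum:
                j = jj
                break
        x += nus[j]
        n_events += 1
        if n_events >= cap:
            capped = True
            cap_time = t
            break
    while gi < len(grid):
        out[gi] = x
        gi += 1
    return out, draws, x, capped, cap_time


# --- public operations ------------------------------------------------------


def _check_sim_args(x0: int, t_end: float, cap: int) -> None:
    if x0 < 0:
        raise ValueError("x0 must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if cap < 1:
        raise ValueError("cap must be >= 1")


def simulate_trajectory(
    system: ReactionSystem,
    x0: int,
    t_end: float,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
) -> Trajectory:
    """Simulate a single SSA trajectory with full event record.

    Stops at ``t_end`` (recording the crossing draw in ``draw_count``) or
    after ``cap`` committed reactions, whichever comes first.  A state with
    zero total propensity rests until ``t_end`` with no further draws.
    """
    _check_sim_args(x0, t_end, cap)
    nus, kinds, rates, guards = system.arrays()
    times, states, draws, capped, cap_time = _sim_events(
        nus, kinds, rates, guards, x0, float(t_end), int(cap), int(seed)
    )
    return Trajectory(
        event_times=times,
        states=states,
        x0=int(x0),
        t_end=float(t_end),
        draw_count=int(draws),
        capped=bool(capped),
        seed=int(seed),
        cap_time=float(cap_time),
    )


def run_ensemble(
    system: ReactionSystem,
    x0: int,
    t_end: float,
    n: int,
    grid: TimeGrid | None = None,
    cap: int = DEFAULT_CAP,
    base_seed: int = 0,
) -> Ensemble:
    """Simulate ``n`` independent trajectories evaluated on a shared grid.

    Trajectory ``i`` uses seed ``base_seed + i``, so the ensemble is
    reproducible and the per-trajectory streams do not depend on execution
    order.  Grid evaluation is right-continuous: each grid time takes the
    state after the last event at or before it.  Capped trajectories carry
    their state at the cap event over the remaining grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_sim_args(x0, t_end, cap)
    if grid is None:
        grid = TimeGrid.log(t_end)
    if abs(grid.t_end - t_end) > 1e-12:
        raise ValueError("grid must end at t_end")
    nus, kinds, rates, guards = system.arrays()
    states_on_grid = np.empty((n, len(grid)), dtype=np.int64)
    draw_counts = np.empty(n, dtype=np.int64)
    final_states = np.empty(n, dtype=np.int64)
    capped_flags = np.empty(n, dtype=bool)
    cap_times = np.empty(n, dtype=np.float64)
    for i in range(n):
        seed_i = (int(base_seed) + i) % 2**31
        row, draws, final, capped, cap_time = _sim_grid(
            nus, kinds, rates, guards, int(x0), float(t_end), int(cap), seed_i, grid.points
        )
        states_on_grid[i] = row
        draw_counts[i] = draws
        final_states[i] = final
        capped_flags[i] = capped
        cap_times[i] = cap_time
    return Ensemble(
        system_name=system.name,
        grid=grid,
        states_on_grid=states_on_grid,
        draw_counts=draw_counts,
        final_states=final_states,
        capped_flags=capped_flags,
        cap_times=cap_times,
        base_seed=int(base_seed),
        cap=int(cap),
    )


def escape_times(source) -> pd.DataFrame:
    """Escape (explosion) proxy times of capped simulations.

    For every trajectory that hit its reaction cap, the time of the
    cap-hitting event is the escape proxy; trajectories that reached
    ``t_end`` first are censored at ``t_end``.  Accepts an :class:`Ensemble`
    or a sequence of :class:`Trajectory`.

    Returns a DataFrame with columns ``time`` and ``censored``.
    """
    if isinstance(source, Ensemble):
        capped = source.capped_flags
        times = np.where(capped, source.cap_times, source.grid.t_end)
        return pd.DataFrame({"time": times, "censored": ~capped})
    times, censored = [], []
    for traj in source:
        if traj.capped:
            times.append(traj.cap_time)
            censored.append(False)
        else:
            times.append(traj.t_end)
            censored.append(True)
    return pd.DataFrame({"time": times, "censored": censored})
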