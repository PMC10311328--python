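"""Truncation-closure method of moments (MoM) for one-species networks.

For a network with reactions (nu_j, a_j) the first two moment equations
under truncation closure (skewness and all higher moments set to zero) read

    dE/dt = sum_j nu_j   ( a_j(E) + a_j''(E) V / 2 )
    dV/dt = sum_j 2 nu_j   a_j'(E) V
          + sum_j nu_j^2 ( a_j(E) + a_j''(E) V / 2 )

For propensities that are polynomials of degree <= 2 the Taylor expansion
around the mean is exact, so truncation closure is the *only* approximation:
the third central moment's influence on the variance equation is dropped.
The right-hand sides are then polynomials in (E, V) with monomials
1, E, E^2, V and E*V; coefficients are kept as exact rationals so that
derived systems can be compared coefficient-for-coefficient against
hand-derived equations.

Blow-up detection: explosive systems (e.g. pure quadratic growth,
dE/dt = E^2) have MoM solutions that diverge at a finite time, mirroring the
finite escape time of the underlying stochastic process.  Integration halts
when E or V crosses a threshold and records the crossing time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import sympy
from scipy.integrate import solve_ivp

from .ssa import TimeGrid
from .systems import ReactionSystem, propensity_poly

__all__ = ["MoMSystem", "MoMSolution", "derive_mom", "integrate_mom"]

#: monomial exponents (i, j) of E^i V^j appearing in the closed equations
_MONOMIALS = ((0, 0), (1, 0), (2, 0), (0, 1), (1, 1))


def _poly_str(coeffs: dict[tuple[int, int], Fraction]) -> str:
    names = {(0, 0): "1", (1, 0): "E", (2, 0): "E^2", (0, 1): "V", (1, 1): "E*V"}
    parts = [f"{c}*{names[m]}" for m, c in sorted(coeffs.items()) if c != 0]
    return " + ".join(parts) if parts else "0"


@dataclass(frozen=True)
class MoMSystem:
    """Closed first-two-moment ODEs of a reaction system.

    ``rhs_E`` and ``rhs_V`` map monomial exponents ``(i, j)`` of ``E^i V^j``
    to exact rational coefficients.
    """

    source: str
    rhs_E: dict[tuple[int, int], Fraction]
    rhs_V: dict[tuple[int, int], Fraction]

    def _eval(self, coeffs, E: float, V: float) -> float:
        return sum(float(c) * E**i * V**j for (i, j), c in coeffs.items())

    def rhs(self, t: float, y) -> list[float]:
        """ODE right-hand side in solve_ivp convention, y = (E, V)."""
        E, V = y
        return [self._eval(self.rhs_E, E, V), self._eval(self.rhs_V, E, V)]

    def as_sympy(self):
        """Return (dE/dt, dV/dt) as sympy expressions in symbols E, V."""
        E, V = sympy.symbols("E V")
        fE = sum(sympy.Rational(c) * E**i * V**j for (i, j), c in self.rhs_E.items())
        fV = sum(sympy.Rational(c) * E**i * V**j for (i, j), c in self.rhs_V.items())
        return sympy.simplify(fE), sympy.simplify(fV)

    def fixed_points(self):
        """Solve dE/dt = dV/dt = 0 symbolically; [] when no fixed point exists."""
        E, V = sympy.symbols("E V")
        fE, fV = self.as_sympy()
        return sympy.solve([fE, fV], [E, V], dict=True)

    def to_json(self) -> str:
        def enc(coeffs):
            return [
                {"E_power": i, "V_power": j, "coefficient": str(c)}
                for (i, j), c in sorted(coeffs.items())
                if c != 0
            ]

        return json.dumps(
            {"source": self.source, "dE_dt": enc(self.rhs_E), "dV_dt": enc(self.rhs_V)},
            indent=2,
        )

    def __str__(self) -> str:
        return (
            f"MoM[{self.source}]: dE/dt = {_poly_str(self.rhs_E)}; "
            f"dV/dt = {_poly_str(self.rhs_V)}"
        )


@dataclass
class MoMSolution:
    """Integrated moment courses, truncated at blow-up when one occurred."""

    times: np.ndarray
    E_tilde: np.ndarray
    V_tilde: np.ndarray
    blowup_time: float | None = None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.times, "E": self.E_tilde, "V": self.V_tilde}).to_csv(
            path, index=False
        )


def derive_mom(system: ReactionSystem, neglect_variance: bool = False) -> MoMSystem:
    """Derive the truncation-closed moment ODEs of a reaction system.

    With ``neglect_variance`` the variance's influence on the mean equation
    is additionally dropped (the crudest closure: dE/dt = sum nu_j a_j(E)).
    Propensity guards are ignored -- they are not polynomial and only act at
    copy numbers below the guard.
    """
    rhs_E = {m: Fraction(0) for m in _MONOMIALS}
    rhs_V = {m: Fraction(0) for m in _MONOMIALS}
    for r in system.reactions:
        p0, p1, p2 = propensity_poly(r)  # a(x) = p0 + p1 x + p2 x^2, exact
        nu = Fraction(r.nu)
        # a(E) + a''(E) V / 2 = p0 + p1 E + p2 E^2 + p2 V
        rhs_E[(0, 0)] += nu * p0
        rhs_E[(1, 0)] += nu * p1
        rhs_E[(2, 0)] += nu * p2
        rhs_E[(0, 1)] += nu * p2
        # 2 nu a'(E) V = 2 nu (p1 + 2 p2 E) V
        rhs_V[(0, 1)] += 2 * nu * p1
        rhs_V[(1, 1)] += 4 * nu * p2
        # nu^2 (a(E) + a''(E) V / 2)
        rhs_V[(0, 0)] += nu**2 * p0
        rhs_V[(1, 0)] += nu**2 * p1
        rhs_V[(2, 0)] += nu**2 * p2
        rhs_V[(0, 1)] += nu**2 * p2
    if neglect_variance:
        rhs_E[(0, 1)] = Fraction(0)
        rhs_E[(1, 1)] = Fraction(0)
    return MoMSystem(source=system.name, rhs_E=rhs_E, rhs_V=rhs_V)


def integrate_mom(
    mom: MoMSystem,
    E0: float,
    V0: float,
    grid: TimeGrid | np.ndarray,
    blowup_threshold: float = 1e8,
    rtol: float = 1e-9,
    mean_only: bool = False,
) -> MoMSolution:
    """Integrate the moment ODEs on a time grid with blow-up detection.

    Uses an adaptive Runge-Kutta scheme (rtol <= 1e-9 by default).
    Integration terminates the first time E or V crosses
    ``blowup_threshold``; the crossing time, localized by the integrator's
    root finder on the final step, is recorded as ``blowup_time`` and the
    reported courses stop there.  A non-finite right-hand side before the
    threshold is also reported as blow-up rather than raised.

    With ``mean_only`` only the mean equation is integrated (the variance is
    frozen at ``V0``, and the blow-up event watches the mean alone).  This
    is the natural mode for the variance-neglected closure, whose mean
    equation is autonomous; for explosive systems it pins the recorded
    blow-up time to the divergence of the mean rather than to whichever
    closed moment happens to cross the threshold first.
    """
    if E0 < 0 or V0 < 0:
        raise ValueError("initial moments must be nonnegative")
    times = grid.points if isinstance(grid, TimeGrid) else np.asarray(grid, dtype=float)

    if mean_only:

        def guarded_rhs(t, y):
            dE, _ = mom.rhs(t, [y[0], V0])
            return [dE if np.isfinite(dE) else 0.0]

        def blowup(t, y):
            return blowup_threshold - y[0]

        y0 = [float(E0)]
    else:

        def guarded_rhs(t, y):
            dE, dV = mom.rhs(t, y)
            if not (np.isfinite(dE) and np.isfinite(dV)):
                # freeze the state: the blow-up event below has already fired
                # or will fire at this step; a NaN would abort the solver
                return [0.0, 0.0]
            return [dE, dV]

        def blowup(t, y):
            return blowup_threshold - max(y[0], y[1])

        y0 = [float(E0), float(V0)]

    blowup.terminal = True
    blowup.direction = -1

    with np.errstate(over="ignore", invalid="ignore"):
        sol = solve_ivp(
            guarded_rhs,
            (times[0], times[-1]),
            y0,
            t_eval=times,
            rtol=rtol,
            atol=1e-12,
            events=[blowup],
            dense_output=False,
        )
    blowup_time = None
    if sol.status == 1 and len(sol.t_events[0]) > 0:
        blowup_time = float(sol.t_events[0][0])
    elif not sol.success:
        raise RuntimeError(f"moment integration failed: {sol.message}")
    E = sol.y[0]
    V = sol.y[1] if not mean_only else np.full_like(E, float(V0))
    # the integrator may report variances a hair below zero at machine level
    V = np.where((V < 0) & (V > -1e-9), 0.0, V)
    return MoMSolution(times=sol.t, E_tilde=E, V_tilde=V, blowup_time=blowup_time)
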