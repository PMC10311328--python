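"""One-species chemical reaction networks with polynomial propensities.

A reaction network here is a list of reactions, each changing the molecule
count ``x`` by ``nu`` (+1 or -1) and firing at rate ``c * f(x)``, where the
form of ``f`` is one of four degree-<=2 polynomials.  An optional guard makes
the propensity vanish below a minimum copy number, which is how an absorbing
state at small ``x`` can be avoided or introduced deliberately.

The module ships the four benchmark networks used throughout the package:

``P``
    Immigration-death process (birth at constant rate 10, death at rate x).
    Converges to a Poisson(10) equilibrium -- mild randomness.
``W``
    Quadratic birth-death network with mass-action propensities x(x-1) and a
    unit-rate immigration reaction.  Its equilibrium is fat-tailed: the
    moment series diverge and no expectation or variance exists.
``ideal``
    The idealized quadratic birth-death system with pure x^2 propensities and
    a [x>=2] guard on the death reaction; its equilibrium is exactly the
    inverse-square law P(k) = 6/(pi k)^2.
``pure_growth``
    A single birth reaction with quadratic propensity; every trajectory
    explodes (performs infinitely many reactions) in finite time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Reaction",
    "ReactionSystem",
    "Pmf",
    "propensity",
    "total_propensity",
    "build_system",
    "steady_state_residual",
    "system_from_yaml",
]

#: propensity form -> integer code used by the compiled SSA kernels
KIND_CODES = {
    "constant": 0,
    "linear": 1,
    "pure_quadratic": 2,
    "mass_action_2": 3,
}


@dataclass(frozen=True)
class Reaction:
    """A single reaction channel of a one-species network.

    Parameters
    ----------
    nu
        State change when the reaction fires; +1 or -1 for every system here.
    kind
        Propensity form: ``constant`` (f=1), ``linear`` (f=x),
        ``pure_quadratic`` (f=x^2) or ``mass_action_2`` (f=x(x-1), the
        law-of-mass-action educt count for a second-order reaction).
    rate
        Nonnegative rate constant c (1/s).
    guard_min
        Optional minimum copy number: the propensity is 0 whenever
        ``x < guard_min``.
    """

    nu: int
    kind: str
    rate: float
    guard_min: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KIND_CODES:
            raise ValueError(f"unknown propensity kind {self.kind!r}")
        if not np.isfinite(self.rate) or self.rate < 0:
            raise ValueError("rate must be a finite nonnegative number")
        if self.nu not in (-1, +1):
            raise ValueError("nu must be -1 or +1 for one-species birth-death networks")


@dataclass(frozen=True)
class ReactionSystem:
    """An ordered collection of :class:`Reaction` channels (one species)."""

    name: str
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        if len(self.reactions) < 1:
            raise ValueError("a reaction system needs at least one reaction")
        object.__setattr__(self, "reactions", tuple(self.reactions))

    # --- array views consumed by the compiled SSA kernels -----------------
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (nus, kind codes, rates, guards) as flat numpy arrays."""
        nus = np.array([r.nu for r in self.reactions], dtype=np.int64)
        kinds = np.array([KIND_CODES[r.kind] for r in self.reactions], dtype=np.int64)
        rates = np.array([r.rate for r in self.reactions], dtype=np.float64)
        guards = np.array(
            [0 if r.guard_min is None else r.guard_min for r in self.reactions],
            dtype=np.int64,
        )
        return nus, kinds, rates, guards


@dataclass
class Pmf:
    """A probability mass function on integers ``k >= k_min``.

    ``prob`` maps each supported state to its probability.  Probabilities
    must be nonnegative and must not sum to more than 1 (up to rounding).
    """

    prob: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, p in self.prob.items():
            if p < 0:
                raise ValueError(f"negative probability at k={k}")
        total = float(sum(self.prob.values()))
        if total > 1 + 1e-12:
            raise ValueError(f"probabilities sum to {total} > 1")

    def __getitem__(self, k: int) -> float:
        try:
            return self.prob[k]
        except KeyError:
            raise KeyError(f"pmf has no value for state {k}") from None

    def __contains__(self, k: int) -> bool:
        return k in self.prob


def _form_value(kind: str, x: int) -> float:
    if kind == "constant":
        return 1.0
    if kind == "linear":
        return float(x)
    if kind == "pure_quadratic":
        return float(x) * float(x)
    if kind == "mass_action_2":
        return float(x) * float(x - 1)
    raise ValueError(f"unknown propensity kind {kind!r}")


def propensity(reaction: Reaction, x: int) -> float:
    """Evaluate a reaction's propensity c*f(x) at copy number ``x``.

    Returns 0 when the guard is active (``x < guard_min``).  Raises for
    negative states, which are outside the configuration space.
    """
    if x < 0:
        raise ValueError(f"state must be nonnegative, got {x}")
    if reaction.guard_min is not None and x < reaction.guard_min:
        return 0.0
    return reaction.rate * _form_value(reaction.kind, x)


def total_propensity(system: ReactionSystem, x: int) -> float:
    """Sum of all reaction propensities at state ``x`` (the SSA exit rate)."""
    return sum(propensity(r, x) for r in system.reactions)


def build_system(name: str, **params: float) -> ReactionSystem:
    """Construct one of the four benchmark networks by name.

    ``P`` and ``W`` and ``pure_growth`` take no parameters; ``ideal`` accepts
    rate constants ``c1`` (guarded x^2 death) and ``c2`` (x^2 birth), both
    defaulting to 1.
    """
    if name == "P":
        if params:
            raise ValueError("System P takes no parameters")
        return ReactionSystem(
            "P",
            (
                Reaction(nu=+1, kind="constant", rate=10.0),
                Reaction(nu=-1, kind="linear", rate=1.0),
            ),
        )
    if name == "W":
        if params:
            raise ValueError("System W takes no parameters")
        return ReactionSystem(
            "W",
            (
                Reaction(nu=-1, kind="mass_action_2", rate=1.0),
                Reaction(nu=+1, kind="mass_action_2", rate=1.0),
                Reaction(nu=+1, kind="constant", rate=1.0),
            ),
        )
    if name == "ideal":
        c1 = float(params.pop("c1", 1.0))
        c2 = float(params.pop("c2", 1.0))
        if params:
            raise ValueError(f"unknown parameters {sorted(params)} for ideal system")
        return ReactionSystem(
            "ideal",
            (
                Reaction(nu=-1, kind="pure_quadratic", rate=c1, guard_min=2),
                Reaction(nu=+1, kind="pure_quadratic", rate=c2),
            ),
        )
    if name == "pure_growth":
        if params:
            raise ValueError("pure_growth takes no parameters")
        return ReactionSystem(
            "pure_growth",
            (Reaction(nu=+1, kind="pure_quadratic", rate=1.0),),
        )
    raise ValueError(f"unknown system name {name!r}")


def steady_state_residual(system: ReactionSystem, pmf: Pmf, x: int) -> float:
    """Evaluate the stationary balance of the master equation at state ``x``.

    Returns ``sum_j a_j(x - nu_j) P(x - nu_j) - sum_j a_j(x) P(x)``, which is
    zero at every state exactly when ``pmf`` is a stationary distribution of
    the network.  The pmf must cover ``x`` and every state one reaction away
    from it; a missing state raises rather than being treated as probability
    zero, because a silent zero would fake balance at truncated supports.
    """
    inflow = 0.0
    for r in system.reactions:
        src = x - r.nu
        if src < 0:
            continue  # no state below 0 exists, nothing can flow in from it
        inflow += propensity(r, src) * pmf[src]
    outflow = total_propensity(system, x) * pmf[x]
    return inflow - outflow


# --- YAML construction ----------------------------------------------------

def system_from_yaml(text: str) -> ReactionSystem:
    """Build a :class:`ReactionSystem` from a YAML config block.

    Expected layout::

        name: my_system
        reactions:
          - {nu: 1, kind: constant, rate: 10.0}
          - {nu: -1, kind: linear, rate: 1.0, guard_min: 2}
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValueError("YAML system config must be a mapping")
    name = doc.get("name")
    raw = doc.get("reactions")
    if not name or not isinstance(raw, Sequence) or not raw:
        raise ValueError("system config needs a 'name' and a nonempty 'reactions' list")
    reactions = []
    for entry in raw:
        reactions.append(
            Reaction(
                nu=int(entry["nu"]),
                kind=str(entry["kind"]),
                rate=float(entry["rate"]),
                guard_min=(int(entry["guard_min"]) if "guard_min" in entry and entry["guard_min"] is not None else None),
            )
        )
    return ReactionSystem(str(name), tuple(reactions))


# exact rational propensity coefficients, used by the moment engine ---------

def propensity_poly(reaction: Reaction) -> tuple[Fraction, Fraction, Fraction]:
    """Coefficients (p0, p1, p2) of a(x) = c*(p0 + p1 x + p2 x^2) as exact rationals.

    Guards are ignored: they only matter at copy numbers below ``guard_min``
    and have no smooth polynomial representation, so moment equations treat
    the propensity as its polynomial form everywhere.
    """
    c = Fraction(reaction.rate).limit_denominator(10**12)
    if reaction.kind == "constant":
        p = (Fraction(1), Fraction(0), Fraction(0))
    elif reaction.kind == "linear":
        p = (Fraction(0), Fraction(1), Fraction(0))
    elif reaction.kind == "pure_quadratic":
        p = (Fraction(0), Fraction(0), Fraction(1))
    elif reaction.kind == "mass_action_2":
        p = (Fraction(0), Fraction(-1), Fraction(1))
    else:  # pragma: no cover - constructor already validates
        raise ValueError(reaction.kind)
    return (c * p[0], c * p[1], c * p[2])
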