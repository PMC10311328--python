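"""Fat-tail diagnostics for SSA trajectory ensembles.

Three complementary views of whether a reaction network's distribution is
developing a fat tail:

* the empirical pmf at a time point and the slope of its tail in a log-log
  plot -- a polynomial tail is a straight line, and the slope decides which
  moments can exist (slope >= -2: not even a mean; -3 <= slope < -2: a mean
  but no variance; steeper: the first two moments may exist);
* the distribution of per-trajectory step counts -- an explosive network
  transfers the fat tail of its state distribution onto the number of
  reactions needed to simulate a fixed time span, which is the
  hardware-independent proxy for run time;
* parity and resting statistics -- trajectories of a quadratic birth-death
  network with slow immigration spend long stretches resting at copy
  number 1, where the step count to cross the horizon is forced odd.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ssa import Ensemble

__all__ = [
    "PmfEstimate",
    "TailReport",
    "StepStats",
    "empirical_pmf",
    "tail_exponent",
    "step_stats",
]


@dataclass
class PmfEstimate:
    """Relative state frequencies of an ensemble at one time point."""

    time: float
    support: np.ndarray
    freq: np.ndarray
    n_effective: int
    n_excluded: int

    @classmethod
    def from_samples(cls, samples, time: float = float("nan"), n_excluded: int = 0) -> "PmfEstimate":
        """Treat a flat sample of states as one ensemble column."""
        x = np.asarray(samples, dtype=np.int64).ravel()
        if len(x) == 0:
            raise ValueError("samples must be nonempty")
        support, counts = np.unique(x, return_counts=True)
        return cls(
            time=time,
            support=support,
            freq=counts / len(x),
            n_effective=len(x),
            n_excluded=n_excluded,
        )

    @classmethod
    def from_exact(cls, support, prob, time: float = float("nan")) -> "PmfEstimate":
        """Wrap an exact pmf table so it can be fed to the tail fit."""
        return cls(
            time=time,
            support=np.asarray(support, dtype=np.int64),
            freq=np.asarray(prob, dtype=np.float64),
            n_effective=0,
            n_excluded=0,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"k": self.support, "frequency": self.freq}).to_csv(path, index=False)


@dataclass
class TailReport:
    """OLS tail slope of a pmf in log-log coordinates and its verdict.

    ``classification`` is one of ``"no mean"``, ``"no variance"``,
    ``"all moments may exist"`` or ``"inconclusive"``; the verdict uses the
    95% confidence band of the slope, and a band that straddles one of the
    thresholds (-2, -3) is reported as inconclusive rather than forced.
    """

    exponent: float
    se: float
    fit_range: tuple[int, int]
    n_points: int
    classification: str

    def to_json(self) -> str:
        d = asdict(self)
        d["fit_range"] = list(d["fit_range"])
        return json.dumps(d, indent=2)


@dataclass
class StepStats:
    """Step-count and final-state statistics of an ensemble."""

    mean_steps: float  # over uncapped trajectories
    frac_exceeding: float  # draw_count > R, capped runs count as exceeding
    odd_fraction: float  # odd draw_count among uncapped trajectories
    frac_final_at: float  # state at t_end == x_star (capped: counted as not)
    R: int
    x_star: int
    n: int
    n_capped: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def empirical_pmf(ensemble: Ensemble, t: float) -> PmfEstimate:
    """Relative frequencies of the uncapped trajectories' states at grid time ``t``.

    Capped trajectories are excluded (their grid states after the cap event
    are stale) and the exclusion count is reported.
    """
    column = ensemble.column(t)  # raises if t is not a grid point
    keep = ~ensemble.capped_flags
    if not keep.any():
        raise ValueError("all trajectories capped; no pmf estimate at this time")
    est = PmfEstimate.from_samples(column[keep], time=t)
    est.n_excluded = int((~keep).sum())
    return est


def tail_exponent(
    pmf: PmfEstimate,
    k_lo: int | None = None,
    k_hi: int | None = None,
    min_count: int = 5,
) -> TailReport:
    """Fit the log-log tail slope of a pmf estimate by ordinary least squares.

    The fit uses nonzero-frequency bins with ``k_lo <= k <= k_hi`` (zero
    bins are dropped; log 0 is undefined and pseudocounts would bias the
    slope).  When no range is given, ``k_lo`` defaults to the 90th
    percentile of the distribution and ``k_hi`` to the largest state with at
    least ``min_count`` observations, so the fit sits in the tail but not in
    the one-off extreme order statistics.

    Fewer than 4 usable points yields an explicit ``"inconclusive"`` report
    with NaN slope, never a silent fit.
    """
    support = np.asarray(pmf.support)
    freq = np.asarray(pmf.freq)
    if k_lo is None:
        cdf = np.cumsum(freq) / freq.sum()
        k_lo = int(support[np.searchsorted(cdf, 0.9)])
    if k_hi is None:
        if pmf.n_effective > 0:
            counts = freq * pmf.n_effective
            heavy = support[counts >= min_count]
            k_hi = int(heavy.max()) if len(heavy) else int(support.max())
        else:
            k_hi = int(support.max())
    mask = (support >= max(k_lo, 1)) & (support <= k_hi) & (freq > 0)
    ks = support[mask]
    if len(np.unique(ks)) < 4:
        return TailReport(
            exponent=float("nan"),
            se=float("nan"),
            fit_range=(int(k_lo), int(k_hi)),
            n_points=int(len(ks)),
            classification="inconclusive",
        )
    fit = stats.linregress(np.log(ks.astype(float)), np.log(freq[mask]))
    slope, se = float(fit.slope), float(fit.stderr)
    lo, hi = slope - 1.96 * se, slope + 1.96 * se
    eps = 1e-9  # keep exact boundary slopes (e.g. a perfect k^-2 fit) off the knife edge
    if lo >= -2 - eps:
        label = "no mean"
    elif hi < -2 and lo >= -3 - eps:
        label = "no variance"
    elif hi < -3:
        label = "all moments may exist"
    else:
        label = "inconclusive"
    return TailReport(
        exponent=slope,
        se=se,
        fit_range=(int(k_lo), int(k_hi)),
        n_points=int(len(ks)),
        classification=label,
    )


def step_stats(ensemble: Ensemble, R: int = 175, x_star: int = 1) -> StepStats:
    """Step-count distribution summaries of an ensemble.

    ``mean_steps`` and ``odd_fraction`` use uncapped trajectories only (a
    capped count is a lower bound, not an observation).  Capped trajectories
    do count toward ``frac_exceeding`` whenever the cap exceeds ``R`` --
    they performed at least ``cap`` reactions -- and count as *not* resting
    at ``x_star``.  Both conventions can only lower the reported fractions.
    """
    capped = ensemble.capped_flags
    uncapped = ~capped
    draw = ensemble.draw_counts
    n = ensemble.n
    mean_steps = float(draw[uncapped].mean()) if uncapped.any() else float("nan")
    exceeding = (draw > R) & (uncapped | (ensemble.cap > R))
    frac_exceeding = float(exceeding.sum() / n)
    odd_fraction = float((draw[uncapped] % 2 == 1).mean()) if uncapped.any() else float("nan")
    at_star = uncapped & (ensemble.final_states == x_star)
    return StepStats(
        mean_steps=mean_steps,
        frac_exceeding=frac_exceeding,
        odd_fraction=odd_fraction,
        frac_final_at=float(at_star.sum() / n),
        R=int(R),
        x_star=int(x_star),
        n=int(n),
        n_capped=int(capped.sum()),
    )
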