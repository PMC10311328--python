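"""Bias-free sample moment estimators and their convergence diagnostics.

The estimators are the standard ones,

    mean_n = (1/n) sum_{i<=n} x_i,        var_n = (1/(n-1)) sum_{i<=n} (x_i - mean_n)^2,

computed as *prefix series*: one estimate per sample count n, so that the
stability of the series over growing n can be inspected.  For a mildly
random system the series settles (central limit theorem); for a fat-tailed
one it keeps jumping, because single disruptive samples rewrite the whole
estimate.  The dominance diagnostic quantifies this: the largest log-scale
jump between consecutive prefix estimates, and the largest single-sample
share of the final variance (or absolute-mean) sum.

The prefix series is computed in a single streaming pass (Welford's
update), which agrees with the two-pass textbook formulas to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ssa import Ensemble

__all__ = [
    "MomentSeries",
    "DominanceReport",
    "prefix_moments",
    "timecourse_moments",
    "dominance_diagnostic",
]


@dataclass
class MomentSeries:
    """Prefix mean/variance estimates over growing sample count.

    ``var_prefix[0]`` (the n=1 entry) is NaN: a single sample has no
    variance estimate under the n-1 denominator.
    """

    samples: np.ndarray
    n_values: np.ndarray
    mean_prefix: np.ndarray
    var_prefix: np.ndarray
    max_gap_index: int
    max_gap_size: float


@dataclass
class DominanceReport:
    """Largest prefix-series jump and single-sample dominance shares."""

    index: int  # 1-based sample index at which the flagged gap occurs
    gap: float  # |log ratio| of consecutive prefix estimates at that index
    dominance_ratio: float  # largest single-sample share of the final variance sum
    mean_index: int
    mean_gap: float
    mean_dominance_ratio: float  # largest |x_i| / sum |x_j|
    variance_series_valid: bool  # False when gaps had to fall back to the mean series


def _log_gaps(values: np.ndarray) -> tuple[int, float]:
    """Largest |log v_i - log v_{i-1}| over consecutive positive entries.

    Returns (0-based index of the later entry, gap); (-1, 0.0) when no
    consecutive positive pair exists.
    """
    best_i, best = -1, 0.0
    logs = np.full(len(values), np.nan)
    pos = values > 0
    logs[pos] = np.log(values[pos])
    d = np.abs(np.diff(logs))
    if len(d) and not np.all(np.isnan(d)):
        best_i = int(np.nanargmax(d)) + 1
        best = float(d[best_i - 1])
    return best_i, best


def prefix_moments(samples) -> MomentSeries:
    """Streaming prefix mean and variance estimates of an ordered sample."""
    x = np.asarray(samples, dtype=np.float64).ravel()
    N = len(x)
    if N == 0:
        raise ValueError("samples must be nonempty")
    mean = np.empty(N)
    var = np.empty(N)
    m, m2 = 0.0, 0.0
    for i in range(N):
        delta = x[i] - m
        m += delta / (i + 1)
        m2 += delta * (x[i] - m)
        mean[i] = m
        var[i] = m2 / i if i >= 1 else np.nan
    gap_index, gap = _log_gaps(var[1:])
    if gap_index >= 0:
        gap_index += 2  # shift to 1-based sample count (var starts at n=2)
    else:
        gap_index, gap = _log_gaps(np.abs(mean))
        gap_index += 1
    return MomentSeries(
        samples=x,
        n_values=np.arange(1, N + 1),
        mean_prefix=mean,
        var_prefix=var,
        max_gap_index=int(gap_index),
        max_gap_size=float(gap),
    )


def timecourse_moments(ensemble: Ensemble) -> pd.DataFrame:
    """Full-ensemble mean and variance estimates at every grid time.

    Capped trajectories are excluded (their states after the cap are stale)
    and counted in ``n_excluded``; excluding them biases tails downward,
    since the capped trajectories are exactly the large-copy-number ones.
    When fewer than one (mean) or two (variance) trajectories remain, the
    estimate is NaN.
    """
    keep = ~ensemble.capped_flags
    n_kept = int(keep.sum())
    n_excluded = ensemble.n - n_kept
    t = ensemble.grid.points
    if n_kept == 0:
        nan = np.full(len(t), np.nan)
        return pd.DataFrame({"t": t, "mean": nan, "variance": nan, "n": 0, "n_excluded": n_excluded})
    states = ensemble.states_on_grid[keep].astype(np.float64)
    mean = states.mean(axis=0)
    var = states.var(axis=0, ddof=1) if n_kept >= 2 else np.full(len(t), np.nan)
    return pd.DataFrame(
        {"t": t, "mean": mean, "variance": var, "n": n_kept, "n_excluded": n_excluded}
    )


def dominance_diagnostic(series: MomentSeries) -> DominanceReport:
    """Rank how strongly single samples disrupt the prefix estimates.

    The gap at sample i is the absolute log-ratio of consecutive prefix
    variances (falling back to the mean series when a prefix variance is
    nonpositive, e.g. for constant data).  ``dominance_ratio`` is the
    largest single-sample contribution (x_i - mean_N)^2 to the final
    variance sum, in [0, 1]; ``mean_dominance_ratio`` is the analog
    |x_i| / sum|x_j| for the mean.  No thresholds are applied -- the report
    ranks, the caller judges.
    """
    x = series.samples
    N = len(x)
    if N < 2:
        raise ValueError("need at least 2 samples")
    var_defined = series.var_prefix[1:]
    variance_series_valid = bool(np.all(var_defined > 0))
    if variance_series_valid:
        idx, gap = _log_gaps(var_defined)
        idx += 2
    else:
        idx, gap = _log_gaps(np.abs(series.mean_prefix))
        idx += 1
    mean_idx, mean_gap = _log_gaps(np.abs(series.mean_prefix))
    mean_idx += 1

    dev2 = (x - series.mean_prefix[-1]) ** 2
    total = dev2.sum()
    dom = float(dev2.max() / total) if total > 0 else 0.0
    abs_x = np.abs(x)
    abs_total = abs_x.sum()
    mean_dom = float(abs_x.max() / abs_total) if abs_total > 0 else 0.0
    return DominanceReport(
        index=int(idx),
        gap=float(gap),
        dominance_ratio=dom,
        mean_index=int(mean_idx),
        mean_gap=float(mean_gap),
        mean_dominance_ratio=mean_dom,
        variance_series_valid=variance_series_valid,
    )
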