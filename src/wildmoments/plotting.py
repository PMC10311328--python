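"""Thin plotting layer over the diagnostic tables (optional to use)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import PmfEstimate, TailReport
from .estimators import MomentSeries
from .ssa import Ensemble

__all__ = ["plot_prefix_series", "plot_pmf_loglog", "plot_step_histogram"]


def plot_prefix_series(series: MomentSeries, log_scale: bool = False, ax=None):
    """Prefix mean and variance estimates over growing sample count."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.n_values, series.mean_prefix, ".", ms=2, color="tab:red", label="mean")
    ax.plot(series.n_values, series.var_prefix, ".", ms=2, color="gray", label="variance")
    if log_scale:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("included samples n")
    ax.set_ylabel("prefix estimate")
    ax.legend()
    return ax


def plot_pmf_loglog(pmf: PmfEstimate, tail: TailReport | None = None, ax=None):
    """Empirical pmf in log-log coordinates, with the fitted tail line."""
    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(pmf.support, pmf.freq, "o", ms=3)
    if tail is not None and np.isfinite(tail.exponent):
        k = np.geomspace(max(tail.fit_range[0], 1), tail.fit_range[1], 50)
        anchor_mask = pmf.support >= tail.fit_range[0]
        if anchor_mask.any():
            k0 = pmf.support[anchor_mask][0]
            f0 = pmf.freq[anchor_mask][0]
            ax.loglog(k, f0 * (k / k0) ** tail.exponent, "k-", label=f"slope {tail.exponent:.2f}")
            ax.legend()
    ax.set_xlabel("copy number k")
    ax.set_ylabel("relative frequency")
    return ax


def plot_step_histogram(ensemble: Ensemble, bins: int = 60, ax=None):
    """Histogram of per-trajectory step counts with its cumulative curve."""
    if ax is None:
        _, ax = plt.subplots()
    draws = ensemble.draw_counts[~ensemble.capped_flags]
    ax.hist(draws, bins=bins, color="tab:red", density=True)
    ax.set_xlabel("SSA steps to reach the horizon")
    ax.set_ylabel("relative frequency")
    ax2 = ax.twinx()
    xs = np.sort(draws)
    ax2.plot(xs, np.arange(1, len(xs) + 1) / len(xs), "k-")
    ax2.set_ylabel("cumulative fraction")
    return ax
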