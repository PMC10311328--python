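"""Closed-form reference distributions and their (possibly divergent) moment series.

The central object is the discrete inverse-square law

    P(x = k) = 6 / (pi k)^2,   k = 1, 2, ...

which is a proper probability measure (the partial sums converge to 1) whose
moment series of every natural order m >= 1 diverge: P(k) k^m sums like the
harmonic series or worse.  A distribution of this kind has no expectation and
no variance, and any attempt to estimate those from samples is chasing a
quantity that does not exist.

The module also provides seeded samplers for three reference cases that
illustrate mild, slow and wild randomness: a normal and a log-normal
distribution sharing the moments E = e and V = e^4 - e^2, and the
inverse-square law itself.  The log-normal parameters mu = 0, sigma^2 = 2 are
the unique log-scale solution of the moment equations
exp(sigma^2/2) = e and (exp(sigma^2) - 1) exp(sigma^2) = e^4 - e^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "inverse_square_pmf",
    "inverse_square_tail",
    "partial_moment_sum",
    "MomentSeriesEvaluation",
    "sample_reference",
    "REFERENCE_MEAN",
    "REFERENCE_VARIANCE",
]

#: shared first two moments of the Figure-style normal / log-normal pair
REFERENCE_MEAN = math.e
REFERENCE_VARIANCE = math.e**4 - math.e**2

#: log-normal log-scale parameters forced by the moments above
_LOGNORMAL_MU = 0.0
_LOGNORMAL_SIGMA = math.sqrt(2.0)

#: exact-inverse-CDF table extent for the inverse-square sampler; beyond this
#: the continuous Pareto tail approximation takes over (see sample_reference)
_TABLE_MAX = 10**6


def inverse_square_pmf(k):
    """Probability of state ``k`` under the inverse-square law 6/(pi k)^2.

    Accepts a positive integer or an integer array; raises on k <= 0, which
    is outside the support.
    """
    arr = np.asarray(k)
    if np.any(arr <= 0):
        raise ValueError("inverse-square support is k >= 1")
    out = 6.0 / (np.pi * arr.astype(np.float64)) ** 2
    return float(out) if np.isscalar(k) or arr.ndim == 0 else out


def inverse_square_tail(K: int) -> tuple[float, float]:
    """Analytic bracket (upper, lower) for the tail sum ``sum_{k>K} 6/(pi k)^2``.

    By integral comparison the remainder lies between 6/(pi^2 (K+1)) and
    6/(pi^2 K).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    c = 6.0 / math.pi**2
    return c / K, c / (K + 1)


@dataclass
class MomentSeriesEvaluation:
    """Partial sums of ``sum_k P(k) k^m`` at a list of cutoffs.

    ``order`` 0 is the normalization series; for a fat-tailed pmf the sums of
    any order m >= 1 grow without bound instead of converging.
    """

    order: int
    cutoffs: list[int]
    partial_sums: list[float]


def partial_moment_sum(pmf, m: int, cutoffs) -> MomentSeriesEvaluation:
    """Evaluate partial moment sums of a pmf up to one or several cutoffs.

    Parameters
    ----------
    pmf
        Either a callable ``pmf(k_array) -> probabilities`` on integer arrays
        (support k >= 1 assumed) or a :class:`~wildmoments.systems.Pmf`-like
        mapping with a ``prob`` dict.
    m
        Moment order; 0 gives the normalization series.
    cutoffs
        A single cutoff K or an increasing list of cutoffs.  Each partial sum
        is the exact finite sum over the pmf's support up to that K.
    """
    if m < 0:
        raise ValueError("moment order must be >= 0")
    Ks = [int(cutoffs)] if np.isscalar(cutoffs) else [int(K) for K in cutoffs]
    if any(K < 1 for K in Ks):
        raise ValueError("cutoffs must be >= 1")
    sums = []
    if callable(pmf):
        for K in Ks:
            total = 0.0
            # chunked vectorized summation, smallest terms first for accuracy
            for lo in range(K, 0, -(10**6)):
                hi = lo
                lo = max(1, lo - 10**6 + 1)
                k = np.arange(lo, hi + 1, dtype=np.float64)
                total += float(np.sum(np.asarray(pmf(k)) * k**m))
            sums.append(total)
    else:
        items = sorted(pmf.prob.items())
        for K in Ks:
            sums.append(float(sum(p * k**m for k, p in items if 1 <= k <= K)))
    return MomentSeriesEvaluation(order=m, cutoffs=Ks, partial_sums=sums)


def _sample_inverse_square(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact inverse-CDF draws from 6/(pi k)^2 with an analytic Pareto tail.

    Cumulative sums are tabulated exactly up to k = 10^6, which covers all
    but ~6e-7 of the probability mass; a uniform draw beyond the table is
    inverted through the continuous tail approximation
    1 - F(k) ~ 6/(pi^2 k).
    """
    k = np.arange(1, _TABLE_MAX + 1, dtype=np.float64)
    cdf = np.cumsum(6.0 / (np.pi * k) ** 2)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    inside = u < cdf[-1]
    out[inside] = np.searchsorted(cdf, u[inside], side="right") + 1
    tail = ~inside
    if np.any(tail):
        c = 6.0 / math.pi**2
        out[tail] = np.ceil(c / (1.0 - u[tail])).astype(np.int64)
    return out


def sample_reference(kind: str, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` seeded samples from one of the three reference distributions.

    ``normal`` and ``lognormal`` share the moments E = e, V = e^4 - e^2 (the
    normal sample may contain negative values; none are truncated).
    ``inverse_square`` draws integers k >= 1 with P(k) = 6/(pi k)^2.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "normal":
        return rng.normal(REFERENCE_MEAN, math.sqrt(REFERENCE_VARIANCE), size=n)
    if kind == "lognormal":
        return rng.lognormal(_LOGNORMAL_MU, _LOGNORMAL_SIGMA, size=n)
    if kind == "inverse_square":
        return _sample_inverse_square(n, rng)
    raise ValueError(f"unknown reference kind {kind!r}")
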