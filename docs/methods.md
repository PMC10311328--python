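# Methods

## Model class

The package treats one-species reaction networks: a state x ∈ ℕ₀ and J
reaction channels, each with a state change ν_j ∈ {−1, +1} and a propensity
a_j(x) = c_j f_j(x), where f_j is one of four polynomial forms of degree at
most two — constant (1), linear (x), pure quadratic (x²) or mass-action
second order (x(x−1), the number of educt pairs). An optional guard sets the
propensity to zero below a minimum copy number, which is how the idealized
quadratic system avoids stepping below its support. The underlying
probability law is the chemical master equation; the package never
integrates it directly (no finite-state-projection or CME solver is in
scope) but works through two summaries of it — exact trajectory sampling
and closed moment equations — plus the stationary balance

    Σ_j a_j(x − ν_j) P̄(x − ν_j) − Σ_j a_j(x) P̄(x) = 0,

which is evaluated as a residual to *verify* a candidate stationary
distribution rather than to solve for one. A missing pmf state raises
instead of contributing zero, since a silent zero would fake balance on a
truncated support.

### Benchmark systems and their rate constants

* **System P** (mild): birth at constant rate 10, death at rate x. Its
  stationary law is Poisson(10); both moments exist and equal 10.
* **System W** (wild): mass-action death 2A→A and birth 2A→3A at unit
  rates, plus immigration at unit rate. The immigration rate and the
  mass-action forms are pinned down by the system's closed moment
  equations, dẼ/dt = 1 and dṼ/dt = 1 + 2(Ẽ(Ẽ−1) + Ṽ): the derivation
  round-trips these equations coefficient-for-coefficient, and that
  round-trip is a unit test. With unit immigration the total propensity is
  at least 1 at every state, so the chain has no absorbing state.
* **Idealized system**: pure x² death guarded by [x ≥ 2] and pure x²
  birth. Its stationary law is exactly the inverse-square distribution,
  verified by the balance residual cancelling algebraically at every state.
* **Pure growth**: a single x² birth. Every trajectory performs infinitely
  many reactions in finite time; its variance-neglected mean equation
  dẼ/dt = Ẽ² blows up at t = 1/Ẽ(0).

## Reference distributions

The inverse-square law P(k) = 6/(πk)² is the canonical moment-free case:
the order-0 series converges to 1 (the tail beyond K is bracketed by
6/(π²(K+1)) and 6/(π²K) via integral comparison), while every series of
order m ≥ 1 diverges — the mean series grows like (6/π²)(ln K + γ).
Sampling uses exact inverse-CDF lookup on tabulated cumulative sums up to
k = 10⁶ (covering all but ≈ 6·10⁻⁷ of the mass) with the continuous Pareto
tail approximation 1 − F(k) ≈ 6/(π²k) inverted analytically beyond the
table; the switchover keeps the table bounded while remaining exact where
the mass lives. The mild/slow reference pair is a normal and a log-normal
distribution sharing mean e and variance e⁴ − e²; the log-normal log-scale
parameters μ = 0, σ² = 2 are the unique solution of the moment equations.
The normal sampler does not truncate negative draws.

## SSA engine

Standard direct method. Conventions that matter:

* **Step counting.** `draw_count` counts waiting-time draws *including* the
  final draw that crosses the horizon and is never committed. Under this
  convention a trajectory that starts and ends at the same state has made an
  even number of ±1 moves plus one crossing draw — an odd total — which is
  the parity signature asserted for system W. Counting committed reactions
  instead would shift every count by one; all quantitative statements about
  step counts have tolerances far wider than that.
* **Caps.** Each trajectory stops after `cap` committed reactions (default
  10 000) and is flagged, never dropped. The cap is what makes explosive
  ensembles finish: an uncapped quadratic-birth trajectory can fire
  arbitrarily many reactions in a fraction of simulated time. The time of
  the cap-hitting event is the escape-time proxy; trajectories that reach
  the horizon first are censored there.
* **Grids.** Ensembles are evaluated on {0} ∪ 1000 logarithmically uniform
  points on [10⁻³ s, t_end] (1001 points total). The lower grid edge is a
  package choice; evaluation is right-continuous (state of the last event
  at or before each grid time), and capped trajectories carry their state
  at the cap event over the remaining grid.
* **Seeding.** Trajectory i of an ensemble uses seed base_seed + i, so
  ensembles are bit-reproducible and independent of execution order.

The inner loops are numba-compiled; a 2000-trajectory capped ensemble of
system W simulates in well under a second.

## Moment engine

For degree-≤2 propensities the second-order Taylor expansion of the moment
equations around the mean is exact, so truncation closure — discarding the
third central moment's influence — is the only approximation. Coefficients
are kept as exact rationals (`fractions.Fraction`) until integration, which
makes the derivation round-trip tests exact rather than approximate.
Propensity guards are ignored in the derivation: they are not polynomial
and act only below the guarded copy number.

Integration uses `scipy.integrate.solve_ivp` (adaptive Runge–Kutta,
rtol 10⁻⁹, atol 10⁻¹²). Blow-up is detected as a terminal event when Ẽ or
Ṽ crosses a threshold (default 10⁸), with the crossing localized by the
solver's root finder on the final step; a non-finite right-hand side before
the threshold is reported as blow-up, not raised. For the variance-neglected
closure the mean equation is autonomous, and `mean_only=True` integrates it
alone with the event watching the mean; this matters for explosive systems,
where the closed variance grows faster than the mean (like (1−t)⁻⁴ against
(1−t)⁻¹ for pure growth) and would otherwise trip the joint threshold first
even though both moments diverge at the same instant. Variances a hair
below zero at machine level (|Ṽ| < 10⁻⁹) are clamped to zero.

## Estimators and diagnostics

* **Prefix moments.** Single-pass Welford updates produce one mean/variance
  estimate per prefix length n; the n = 1 variance is reported as NaN
  (undefined under the n−1 denominator), never as 0. Agreement with the
  two-pass textbook formulas is property-tested.
* **Dominance.** The "gap" at sample i is the absolute log-ratio of
  consecutive prefix variances (the estimators are inspected on log scale
  because fat-tailed estimates span orders of magnitude); when a prefix
  variance is nonpositive the mean series is used and flagged. The
  dominance ratio is the largest single-sample share of the final variance
  sum, with the |x_i|/Σ|x_j| analog for the mean. No threshold converts
  these into a verdict — the distribution of what counts as "disruptive" is
  exactly what fat-tailedness destroys, so the diagnostic ranks and the
  caller judges.
* **Timecourse estimates** exclude capped trajectories and report the
  exclusion count. Capped trajectories are precisely the large-copy-number
  ones, so exclusion biases tails (and variances) downward; every
  exceedance/resting fraction is defined so that this convention can only
  lower it, making the reported lower bounds conservative.
* **Tail exponent.** Ordinary least squares on (log k, log frequency) over
  nonzero bins; zero bins are dropped rather than pseudocounted. The
  default fit range runs from the 90th percentile state to the largest
  state seen at least 5 times, keeping the fit in the tail but out of the
  one-off extreme order statistics. Classification uses the slope's 95%
  band against the thresholds −2 (no mean) and −3 (no variance), with a
  10⁻⁹ margin so that an exact boundary fit (a perfect k⁻² table) is not
  decided by the last floating-point bit; a band straddling a threshold
  yields "inconclusive", and so do fits with fewer than four support
  points.
* **Step statistics.** Mean steps and the odd fraction are computed over
  uncapped trajectories (a capped count is a lower bound, not an
  observation); capped runs count toward the exceedance fraction whenever
  cap > R and count as not resting at the reference state.

## What the generated data does and does not show

All inputs are generated internally: the SSA engine and the reference
samplers play the synthetic-data role. Ensembles are drawn at n = 2000–5000
with reaction caps (default experiments: cap 5000 for system W) rather than
tens of thousands of uncapped runs, because uncapped fat-tailed ensembles
have unbounded total reaction counts; the stochastic claims are therefore
checked as inequalities with conservative capping conventions, and the
deterministic anchors (balance residuals, moment-ODE round trips, blow-up
times) carry the precision. Passing tests demonstrate the estimators' and
diagnostics' behavior on systems whose ground truth is known analytically;
they do not establish how sharply the diagnostics would separate mild from
wild randomness on networks with many species, non-polynomial propensities,
or experimental noise, all of which are out of scope.

## Numerical choices, in brief

Escape-time checks simulate to a horizon (30 s) far beyond any realistic
escape time of the capped pure-growth system so that censoring does not
bias the sample mean being compared against the partial-sum oracle
Σ₁^cap 1/k². Chi-square goodness-of-fit tests lump cells so expected counts
stay ≥ 5 and use α = 0.01. The moment-series cutoff for the normalization
check is K = 10⁷, summed in chunks smallest-terms-first. Rates entering the
exact-rational derivation are converted with a denominator limit of 10¹²,
exact for every benchmark rate.

## Known limitations

One species only; propensity polynomials of degree ≤ 2; truncation closure
only (no normal, log-normal or derivative-matching closures); no
tau-leaping or hybrid simulation; the tail fit is a least-squares slope,
not a Hill-type maximum-likelihood index; outlier tests (Chauvenet, Peirce,
Grubbs) are deliberately not implemented. The step-count convention
(draws including the crossing draw) differs from a committed-reaction count
by one.
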