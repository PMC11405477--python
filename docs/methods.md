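# Methods

## The model family

All three candidate growth maps describe one season of density-dependent
production for a harvested stock, parameterized by the same pair: the
growth multiplier `r = f'(0)` (one-step proliferation rate at low density,
dimensionless) and the carrying capacity `k` (the nonzero fixed point, in
the biomass units of the data):

| model | map | density dependence |
|---|---|---|
| Beverton-Holt | `f_B(s) = r s / (1 + (r-1) s / k)` | compensatory (contest competition) |
| Ricker | `f_R(s) = s r^(1 - s/k)` | over-compensatory (scramble, cannibalism) |
| Hockey-Stick | `f_H(s) = min(r s, k)` | none below the cap, absolute above |

The Ricker map uses the growth-multiplier parameterization rather than the
`exp(a)` form so that `r` means the same thing in all three models; no
conversion helpers are provided.  `GrowthParams` requires `r > 1` strictly
(the Beverton-Holt denominator degenerates at `r = 1`, and populations with
`r <= 1` have no harvestable surplus) and validates finiteness.

## Optimal escapement

Under the stochastic harvested dynamics `x_{t+1} = Z_t f(x_t - h_t)` with
i.i.d. multiplicative noise, the long-run-optimal harvest policy is
constant escapement: let `s*` survive each season, catch the surplus.  For
smooth maps `s*` solves `f'(s*) = 1/rho` with `rho` the per-period discount
factor; for `rho = 1` this is surplus maximization, `argmax f(s) - s`.

* Beverton-Holt: closed form `s* = k (sqrt(r rho) - 1)/(r - 1)`.  At
  `rho = 1` the implementation evaluates the algebraically identical
  `k/(1 + sqrt r)` — the printed form loses ~6 digits to cancellation near
  `r = 1`.
* Ricker: no closed form.  The Reed condition is solved by Brent's method
  on `(epsilon, k/ln r - epsilon)` with `epsilon = 1e-12`, where `f_R'` is
  strictly decreasing, so the bracketed root is unique; tolerance 1e-12
  relative.
* Hockey-Stick: the kink at `k/r` breaks the smooth theory, but for
  `rho = 1` the corner itself is optimal: `s* = k/r`.  A discounted
  Hockey-Stick problem raises `NotImplementedError` rather than guessing a
  policy the undiscounted argument does not cover.

Two special growth rates follow: the Hockey-Stick target crosses the B60
reference point (0.6 k) at `r = 5/3`, and crosses the Beverton-Holt target
at `r = (3 + sqrt 5)/2 ≈ 2.618`.  Both are computed by root-finding and
verified against the closed forms to machine precision in the tests.

### Wrong-model yield loss

`relative_yield` compares deterministic equilibrium catch when the policy
is derived from the wrong model (same `(r, k)`).  The two mistake curves
have closed forms,

    a(r) = [(r-1)^2 (sqrt r + 1)] / [r (2r - 1)(sqrt r - 1)]   (HS rule, BH truth)
    b(r) = r / (1 + sqrt r)                                     (BH rule, HS truth)

which cross at `r = 1.24234`; the Hockey-Stick rule is the cheaper mistake
on `(1.2423, 2.618]`, and the two coincide (both ratios 1) where the
policies merge.  Below the lower crossing the ordering reverses — `a(r)`
vanishes like `4(r-1)` because the Hockey-Stick target approaches `k` —
so tests assert dominance on the exact region rather than all of `(1, 2.2)`.

## Statistical model and likelihood track

All stochasticity is treated as process noise on the growth map:

    x_{t+1} ~ LogNormal(log f_m(x_t - h_t), sigma^2),  t = 1..T-1.

`f_m(e_t)` is thus the *median* next-year biomass.  The simulator uses the
same median-one parameterization (`x_{t+1} = f(e_t) exp(sigma eps_t)`), so
simulation and inference are mutually consistent; the sample mean of the
noise multiplier is `exp(sigma^2/2)`, which the tests verify.

Every model has exactly three parameters `(r, k, sigma)`, so AIC
differences equal twice the log-likelihood differences and Akaike weights
`exp(-dAIC/2)` (normalized) rank models identically to the likelihood.
Maximization is Nelder-Mead inside a box mirroring the Bayesian prior
support — `r in [1, 10]`, `k in [0.1 max x, 10 max x]`, `sigma in
(1e-4, 10]` — with Latin-hypercube multistart (8 by default; `sigma`
sampled on the log scale).  For the Hockey-Stick model the likelihood is
constant in `k` above the maximum observed biomass (no observation probes
the cap), so its `k` box is capped at `max_t x_t`; estimates within 1e-6
of a box edge (relative to box width) are reported in `at_bound`.

## Bayesian track

Priors: `r ~ Uniform[1, 10]`, `k ~ Uniform[0.1 max x, 10 max x]`
(per-series support, as for the MLE box), `sigma ~ HalfCauchy(0, 1)`.

### Sampling

Chains run in `(r, k / max x, log sigma)` coordinates.  Bounded
coordinates are deliberately *not* logit-transformed: these posteriors
often pile mass against a prior bound (e.g. `r` against 10 when the data
favor fast growth), and an unbounded transform stretches that pile into a
tail random walks under-explore.  Instead random-walk proposals are
reflected at the bounds, which preserves proposal symmetry.

The kernel is a mixture, frozen after warmup:

* a Gaussian random walk whose covariance is re-estimated from the
  trailing half of the warmup history and whose scale follows a
  Robbins-Monro recursion toward 30% acceptance;
* with probability 0.3, an independence proposal from a 15-component
  Gaussian mixture fitted to the pooled warmup history of all chains,
  padded with an equal number of prior draws.

The padding is load-bearing.  Weakly identified fits can hold a few
percent of posterior mass in a region detached from the main mode (a
low-`r`/high-`k` sliver where a nearly linear map explains the data); a
proposal fitted only to visited states never proposes there, every chain
misses the same mass, and split-R-hat stays clean while marginals and
evidence are biased.  Prior padding guarantees coverage of the full
support; the Metropolis correction handles the proposal/target mismatch.

Defaults: 4 chains x (3000 warmup + 6000 retained).  Split-R-hat and bulk
ESS (arviz) screen every parameter; a run with any R-hat >= 1.01 is
retried once with doubled length and a fresh derived seed, then returned
*flagged* if still failing.  Downstream operations refuse flagged draws
unless forced; the study runner forces and counts them.

### Evidence

The marginal likelihood is estimated by iterative (Meng-Wong optimal)
bridge sampling in the sampling coordinates: a Gaussian proposal is fitted
by moments to the first half of each chain, the fixed point is iterated on
the second half plus an equal number of proposal draws, in a form that is
overflow-safe for extreme log-ratios.  The Monte-Carlo standard error
combines the proposal-side variance with a posterior-side variance whose
sample size is replaced by the ESS of the bridge integrand (chain draws
are autocorrelated).  Model probabilities assume equal prior model
weights.

The validation lever is a deterministic quadrature oracle (tests and the
acceptance script): trapezoid rules over `(r, k)` — robust to the
Hockey-Stick kink surface, which defeats Gauss-Legendre — and
Gauss-Legendre in `log sigma` truncated at the half-Cauchy 0.9999
quantile.  Node counts (600 x 600 x 120) were frozen after grid-refinement
checks showed stability to ~1e-6 in log Z.  Bridge estimates agree with
the oracle within 3 MC-SEs on a 27-comparison suite.

### Escapement summaries

Posterior escapement is summarized draw-wise: `s*/k` depends only on `r`,
so each draw's fraction is computed (closed form for Beverton-Holt and
Hockey-Stick, Brent root per draw for Ricker) and the median taken, on
both the `k` scale and the `max_t x_t` scale.  Medians of ratios, not
ratios of medians.

## Synthetic data

`simulate_series` draws a harvest proportion from a resampling pool each
step (`h_t = p_t x_t`, keeping escapement positive for any noise), grows
the escapement through the map, and applies lognormal noise.

`generate_base_fishery` emulates a stock-assessment record:
`r ~ Uniform(1.1, 2.0)` (fitted growth-rate medians for real stocks
cluster near 1.3-1.6), `sigma ~ Uniform(0.05, 0.4)`, log-uniform `k` over
`[1e2, 1e5]` (stock scales span decades), `T ~ Uniform{10..80}` years,
`x0` between 20% and 100% of `k`, and a Beta(1.5, 8.5) harvest-proportion
pool (mean exploitation 0.15).  What it does *not* emulate: observation
error, age structure, regime shifts, autocorrelated recruitment, or the
RAM database's metadata and curation quirks.  Passing tests therefore show
the inference machinery behaves correctly when its process-noise
assumption holds — not that the assumption holds for any particular real
fishery.

`make_validation_experiment` rebuilds the simulate-and-refit protocol: for
each generating model, each dataset borrows a random base series' initial
biomass, observed harvest proportions and length, and takes `(r, k,
sigma)` from the final retained value of that series' fitted Markov chain
(approximately one posterior draw; drawing uniformly from the posterior is
available as an option).

## Study conditions and problem sizes

* Parameter recovery: 50 replicates per model at `T = 200`,
  `sigma = 0.05`, true `(r, k) = (2, 100)`, harvest proportions resampled
  from {0, 0.1, ..., 0.5} and `x0 = 20` — a contrast-rich design chosen so
  the growth phase is observed; near-equilibrium-only data leave `r`
  weakly identified regardless of optimizer.
* Evidence validation: 9 problems (3 models x 3 seeds) at `T = 10`,
  bridge vs quadrature within 3 MC-SEs.
* Model recovery: 10 synthetic base fisheries, 10 simulated datasets per
  generating model (30 total), both tracks fitted to all three candidates.
  At these stock-assessment-like lengths and noise levels the evidence
  track shows the documented prior-induced bias — Beverton-Holt wins under
  non-Beverton-Holt truth far above its 1/3 chance level — while Akaike
  weights identify a Ricker or Hockey-Stick truth more often.  A
  paper-scale run (20 per model) reproduced the same pattern more sharply.

## Numerical choices and edge cases

* Zero escapement is filtered out along with negative (log f(0) is
  undefined); the final year's escapement never enters the likelihood and
  is ignored by the filter.
* The deterministic-data screen (LOWESS R^2 of `log x_{t+1}` on `e_t`,
  span `max(0.2, 3/n)`, no robustness iterations, threshold 0.999) is an
  automated proxy for manual curation of model-generated assessment
  output; it is advisory by default and only drops series when explicitly
  enabled.
* `log_likelihood` returns `-inf` (not an exception) when the model
  predicts zero growth for an observed positive biomass, so optimizers can
  back away.
* Exact ties in "best model" or "most conservative model" (difference
  below 1e-12) share credit equally and are counted, keeping win fractions
  summing to one.
* Hockey-Stick growth is defined everywhere (`min` is total); only the
  derivative raises at the corner, within 1e-12 k of `k/r`.

## Known limitations

* Single-species, stationary, one-lag dynamics with two equilibria; no
  Allee effects, age structure, time-varying parameters, or observation
  error.  The process-noise assumption is what makes Reed-style constant
  escapement optimal, and the fits inherit it.
* Discounted Hockey-Stick policies are not supported (no derivation for
  `rho < 1`).
* For Hockey-Stick datasets whose likelihood is flat in `k` above the
  observed maximum, posterior escapement depends on the `k` prior; no
  correction is applied.
* MLE standard errors are not computed.
* The automated deterministic-series screen approximates, but cannot
  replicate, visual curation of real assessment databases.
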