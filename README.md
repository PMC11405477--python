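# escapefit

Optimal-escapement harvest analysis and density-dependent model selection
for fishery biomass/catch time series.

Most of the world's fishery sustainability targets rest on two classic
stock-recruitment models — Beverton-Holt, `f_B(s) = rs/(1+(r-1)s/k)`, and
Ricker, `f_R(s) = s·r^(1−s/k)` — which both recommend maintaining roughly
40–50% of carrying capacity no matter how fast the species grows.  The
piecewise-linear Hockey-Stick model, `f_H(s) = min(rs, k)`, breaks that
consensus: its undiscounted optimal escapement is

    s*_H = k / r,

so for slow-growing stocks (`r < 5/3`) it recommends maintaining *more*
than 60% of carrying capacity — above the widely used B60 reference point.
Whether that matters in practice depends on whether the Hockey-Stick model
fits real data as well as the classics, which is a model-selection
question.  `escapefit` is aimed at quantitative fisheries scientists and
ecological modellers who want to ask it of their own biomass/catch series.

The package provides:

* the three growth models under a shared `(r, k)` parameterization, their
  Reed-style optimal escapement rules (`f'(s*) = 1/ρ`; closed forms where
  they exist, bracketed root-finding for Ricker), and the equilibrium
  yield lost when a policy is derived from the wrong model;
* a lognormal process-noise likelihood
  `x_{t+1} ~ LogNormal(log f(x_t − h_t), σ²)` with maximum-likelihood
  fitting and Akaike weights;
* a Bayesian track — reference priors `r ~ U[1,10]`,
  `k ~ U[0.1·max x, 10·max x]`, `σ ~ HalfCauchy(0,1)`, adaptive-Metropolis
  posterior sampling with convergence screening, bridge-sampling marginal
  likelihoods and posterior model probabilities;
* a synthetic-data generator for the stochastic harvested dynamics
  `x_{t+1} = f(x_t − h_t)·e^{σε_t}` with resampled harvest proportions,
  plus a simulate-and-refit experiment that measures how often each
  inference track recovers a known true model;
* a study runner that fits every series both ways and reports which model
  wins, how often the winner is overwhelming, and which model recommends
  the most conservative escapement.

## Worked example

Fit all three models to a synthetic 54-year fishery generated from
Hockey-Stick dynamics (`r = 1.91`, `k = 21235`, `σ = 0.13`):

```python
from escapefit import (Model, generate_base_fishery, fit_mle,
                       akaike_weights, optimal_escapement,
                       EscapementProblem)

series, design = generate_base_fishery(seed=7, series_id="demo")
fits = {m: fit_mle(m, series, seed=0) for m in Model}
print({m.value: round(w, 3) for m, w in akaike_weights(fits).items()})

hs = fits[Model.HOCKEY_STICK]
policy = optimal_escapement(EscapementProblem(hs.params))
print(f"r̂={hs.params.r:.3f}  k̂={hs.params.k:.0f}  "
      f"s*={policy.s_star:.0f}  s*/k={policy.fraction_of_k:.3f}")
```

Output:

```
{'beverton_holt': 0.021, 'ricker': 0.19, 'hockey_stick': 0.789}
r̂=1.886  k̂=20953  s*=11109  s*/k=0.530
```

The true model gets 79% of the Akaike weight but the others retain real
support — typical for series of this length and noise level.  The fitted
Hockey-Stick policy says to let 53% of carrying capacity escape harvest
(`1/r̂`), while the Beverton-Holt fit of the same data — which pins `r̂`
at the prior's upper bound to mimic the cap — would recommend only 24%.
The spread between those two numbers is the management question the
package quantifies.

A command-line interface wraps the same functions:

```bash
escapefit escapement --model hockey_stick --r 1.4 --k 1000
escapefit plot --out curves.png   # growth maps, s*/k vs r, yield loss
escapefit simulate --model ricker --r 1.8 --k 500 --sigma 0.2 \
    --x0 200 --t 40 --seed 3 --out series.csv
escapefit fit --method mle --input series.csv --out fits.json
escapefit study --input series.csv --out results/
```

Input CSVs have columns `id, year, biomass, catch`; escapement
`e_t = x_t − h_t` is derived, series with non-positive escapement are
filtered out, and a LOWESS-based screen flags suspiciously noise-free
(model-generated) series.

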