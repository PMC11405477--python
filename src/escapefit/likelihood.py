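"""Lognormal process-noise likelihood, MLE, and Akaike-weight comparison.

The statistical model treats all stochasticity as process noise on the
growth map:

    x_{t+1} ~ LogNormal(log f_m(x_t - h_t), sigma^2),   t = 1..T-1,

so ``f_m(e_t)`` is the *median* next-year biomass and sigma is the standard
deviation of log-biomass innovations.  Every candidate model has exactly
three parameters (r, k, sigma), so AIC differences reduce to log-likelihood
differences and Akaike weights rank models identically to the likelihood.

Maximization is by derivative-free Nelder-Mead inside a box matching the
Bayesian prior support (so both inference tracks explore the same space),
with Latin-hypercube multistart.  For the Hockey-Stick model the likelihood
is constant in k above the maximum observed biomass (no observation ever
probes the cap), so k is boxed at max_t x_t there and an estimate pinned at
that edge is reported via ``at_bound``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .data_io import StockSeries
from .models import GrowthParams, Model, growth

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseParams",
    "MleFit",
    "parameter_box",
    "log_likelihood",
    "fit_mle",
    "akaike_weights",
]

R_BOUNDS = (1.0, 10.0)
SIGMA_BOUNDS = (1e-4, 10.0)
N_PARAMS = 3  # r, k, sigma for every model


@dataclass(frozen=True)
class NoiseParams:
    """Process-noise scale sigma of log-biomass innovations.

    sigma = 0 is admitted only so that deterministic trajectories can be
    simulated; the likelihood itself requires sigma > 0.
    """

    sigma: float

    def __post_init__(self) -> None:
        sigma = float(self.sigma)
        if not (math.isfinite(sigma) and sigma >= 0.0):
            raise ValueError(f"sigma must be finite and >= 0, got {sigma}")
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class MleFit:
    """Maximum-likelihood fit of one model to one series."""

    params: GrowthParams
    noise: NoiseParams
    loglik: float
    aic: float
    converged: bool
    at_bound: frozenset = field(default_factory=frozenset)

    @property
    def model(self) -> Model:
        return self.params.model


def parameter_box(model: Model | str, series: StockSeries,
                  ) -> list[tuple[float, float]]:
    """Search box [(r), (k), (sigma)] for one model-series pair.

    k ranges over [0.1 max x, 10 max x] except for the Hockey-Stick model,
    whose upper k bound is max x (the likelihood is flat above it).
    """
    model = Model.coerce(model)
    maxx = series.max_biomass
    k_hi = maxx if model is Model.HOCKEY_STICK else 10.0 * maxx
    return [R_BOUNDS, (0.1 * maxx, k_hi), SIGMA_BOUNDS]


def log_likelihood(params: GrowthParams, noise: NoiseParams,
                   series: StockSeries) -> float:
    """Log-likelihood of a series under one growth model.

    Sums the lognormal log-density of x_{t+1} around median f(e_t) over
    the T-1 transitions.  Returns -inf (rather than raising) when the
    model predicts zero growth for an observed positive biomass, so
    optimizers can back away from the boundary.
    """
    if noise.sigma <= 0.0:
        raise ValueError("likelihood requires sigma > 0")
    e = series.e[:-1]
    if np.any(e < 0.0):
        raise ValueError("series has negative escapement; filter first")
    x_next = series.x[1:]
    fe = np.asarray(growth(params, e), dtype=float)
    if np.any(fe <= 0.0):
        return -math.inf
    log_x = np.log(x_next)
    ll = stats.norm.logpdf(log_x, loc=np.log(fe), scale=noise.sigma)
    return float(np.sum(ll) - np.sum(log_x))


def _objective(theta: np.ndarray, model: Model, series: StockSeries) -> float:
    r, k, sigma = theta
    try:
        params = GrowthParams(model, r, k)
    except ValueError:
        return np.inf
    ll = log_likelihood(params, NoiseParams(sigma), series)
    return -ll if math.isfinite(ll) else np.inf


def fit_mle(model: Model | str, series: StockSeries,
            init: tuple[float, float, float] | None = None,
            n_starts: int = 8, seed: int = 0,
            bound_rtol: float = 1e-6) -> MleFit:
    """Maximize the lognormal process-noise likelihood for one model.

    Runs Nelder-Mead from ``n_starts`` points — the supplied ``init`` (if
    any) plus Latin-hypercube draws over the box — and keeps the best.
    Parameters whose estimate lies within ``bound_rtol`` of a box edge
    (relative to the box width) are reported in ``at_bound``.
    """
    model = Model.coerce(model)
    box = parameter_box(model, series)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(np.clip(np.asarray(init, dtype=float), lo, hi))
    n_lhs = max(n_starts - len(starts), 1)
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    unit = sampler.random(n_lhs)
    # sigma spans 5 decades; sample it on the log scale
    lhs = lo + unit * (hi - lo)
    lhs[:, 2] = np.exp(np.log(lo[2]) + unit[:, 2]
                       * (np.log(hi[2]) - np.log(lo[2])))
    starts.extend(lhs)

    best: optimize.OptimizeResult | None = None
    for x0 in starts:
        res = optimize.minimize(
            _objective, x0, args=(model, series), method="Nelder-Mead",
            bounds=optimize.Bounds(lo, hi),
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000,
                     "maxfev": 6000})
        if not math.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res

    if best is None:
        logger.warning("all MLE starts failed for model %s on series %r",
                       model.value, series.id)
        params = GrowthParams(model, 2.0, series.max_biomass)
        return MleFit(params=params, noise=NoiseParams(1.0),
                      loglik=-math.inf, aic=math.inf, converged=False)

    r, k, sigma = np.clip(best.x, lo, hi)
    at_bound = frozenset(
        name for name, val, b_lo, b_hi in
        (("r", r, *box[0]), ("k", k, *box[1]), ("sigma", sigma, *box[2]))
        if min(val - b_lo, b_hi - val) <= bound_rtol * (b_hi - b_lo))
    loglik = -float(best.fun)
    return MleFit(params=GrowthParams(model, r, k), noise=NoiseParams(sigma),
                  loglik=loglik, aic=2.0 * N_PARAMS - 2.0 * loglik,
                  converged=bool(best.success), at_bound=at_bound)


def akaike_weights(fits: dict[Model, MleFit] | list[MleFit],
                   ) -> dict[Model, float]:
    """Akaike weights w_m = exp(-dAIC_m/2) / sum over candidate models.

    A non-converged fit enters with zero weight (its AIC is +inf), with a
    warning.  With >= 1 finite AIC the weights sum to 1.
    """
    fit_list = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if len(fit_list) < 2:
        raise ValueError("need at least two model fits to compare")
    aics = np.array([f.aic for f in fit_list])
    for f in fit_list:
        if not f.converged or not math.isfinite(f.aic):
            logger.warning("model %s enters Akaike weights with zero weight "
                           "(non-converged fit)", f.model.value)
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValueError("no converged fit among the candidates")
    delta = aics - aics[finite].min()
    w = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    w /= w.sum()
    return {f.model: float(wi) for f, wi in zip(fit_list, w)}
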