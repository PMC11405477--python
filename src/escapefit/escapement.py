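"""Optimal constant-escapement harvest policies and yield-loss analysis.

Under a stochastic harvested population ``x_{t+1} = Z_t f(x_t - h_t)`` with
i.i.d. multiplicative noise, the long-run-optimal policy is a constant
escapement rule: let a fixed biomass s* escape harvest each season and catch
the surplus.  For smooth growth maps s* solves ``f'(s*) = 1/rho`` (rho the
per-period discount factor).  Closed forms:

* Beverton-Holt: ``s* = k (sqrt(r rho) - 1) / (r - 1)``; at rho = 1 this is
  ``k / (1 + sqrt(r))``, always just below k/2.
* Hockey-Stick (undiscounted): ``s* = k / r`` — the corner itself, because
  growth is density-independent below it.  For slow growth (r < 5/3) this
  exceeds the common B60 target of 0.6 k.
* Ricker: no closed form; the unique root of ``f_R'(s) = 1/rho`` on
  (0, k/ln r) is found by bracketed root-finding.

The Hockey-Stick and Beverton-Holt escapements cross at r = (3+sqrt(5))/2:
below it the Hockey-Stick policy is the more conservative one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .models import GrowthParams, Model, growth

__all__ = [
    "EscapementProblem",
    "EscapementPolicy",
    "optimal_escapement",
    "crossing_growth_rate",
    "b60_boundary_growth_rate",
    "equilibrium_yield",
    "relative_yield",
]


@dataclass(frozen=True)
class EscapementProblem:
    """A growth model plus the economic discount factor rho in (0, 1].

    rho = 1 (the default, and the headline case throughout) means no
    discounting of future harvest.
    """

    params: GrowthParams
    rho: float = 1.0

    def __post_init__(self) -> None:
        rho = float(self.rho)
        if not (0.0 < rho <= 1.0):
            raise ValueError(f"discount factor must lie in (0, 1], got {rho}")
        object.__setattr__(self, "rho", rho)


@dataclass(frozen=True)
class EscapementPolicy:
    """An optimal escapement target s* with its dimensionless scaling."""

    s_star: float
    model: Model
    fraction_of_k: float = field(default=float("nan"))


def _ricker_escapement_fraction(r: float, rho: float) -> float:
    # root of r**(1-u) (1 - u ln r) = 1/rho in u = s/k on (0, 1/ln r);
    # f_R' is strictly decreasing there, so the bracketed root is unique.
    lnr = math.log(r)

    def g(u: float) -> float:
        return r ** (1.0 - u) * (1.0 - u * lnr) - 1.0 / rho

    lo, hi = 1e-12, 1.0 / lnr - 1e-12
    if g(lo) <= 0.0:  # pragma: no cover - unreachable for r > 1, rho <= 1
        raise ValueError("no positive Ricker escapement for these parameters")
    return brentq(g, lo, hi, xtol=1e-14, rtol=1e-12)


def optimal_escapement(problem: EscapementProblem) -> EscapementPolicy:
    """Solve for the optimal escapement s* of a growth model.

    Raises
    ------
    NotImplementedError
        For a discounted (rho < 1) Hockey-Stick problem: the corner policy
        argument behind s* = k/r covers only the undiscounted case, and no
        discounted analogue is assumed here.
    """
    p, rho = problem.params, problem.rho
    r, k = p.r, p.k
    if p.model is Model.BEVERTON_HOLT:
        root = math.sqrt(r * rho)
        if root <= 1.0:
            raise ValueError(
                f"no positive escapement: requires r*rho > 1, got {r * rho}")
        if rho == 1.0:
            # algebraically (sqrt r - 1)/(r - 1); this form avoids the
            # catastrophic cancellation of the printed one near r = 1
            s = k / (1.0 + math.sqrt(r))
        else:
            s = k * (root - 1.0) / (r - 1.0)
    elif p.model is Model.HOCKEY_STICK:
        if abs(rho - 1.0) > 1e-12:
            raise NotImplementedError(
                "discounted Hockey-Stick escapement is not supported; the "
                "corner rule s* = k/r holds for rho = 1 only")
        s = k / r
    else:
        s = k * _ricker_escapement_fraction(r, rho)
    return EscapementPolicy(s_star=s, model=p.model, fraction_of_k=s / k)


def escapement_fraction(model: Model | str, r, rho: float = 1.0) -> np.ndarray:
    """Vectorized s*/k as a function of r alone (scale-free form).

    The optimal escapement divided by carrying capacity depends only on
    (r, rho) for all three models, which makes posterior summaries over
    (r, k) draws cheap: compute u(r) = s*/k once per draw and rescale.
    """
    model = Model.coerce(model)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if model is Model.BEVERTON_HOLT:
        out = (1.0 / (1.0 + np.sqrt(r)) if rho == 1.0
               else (np.sqrt(r * rho) - 1.0) / (r - 1.0))
    elif model is Model.HOCKEY_STICK:
        if abs(rho - 1.0) > 1e-12:
            raise NotImplementedError("discounted Hockey-Stick escapement")
        out = 1.0 / r
    else:
        out = np.array([_ricker_escapement_fraction(ri, rho) for ri in r])
    return out


def crossing_growth_rate() -> float:
    """Growth rate where Hockey-Stick and Beverton-Holt escapements cross.

    Solves 1/r = 1/(1 + sqrt(r)) numerically; equals (3 + sqrt(5))/2.
    Below this r the Hockey-Stick target is the more conservative of the two.
    """
    return brentq(lambda r: r - 1.0 - math.sqrt(r), 1.5, 5.0,
                  xtol=1e-15, rtol=4 * np.finfo(float).eps)


def b60_boundary_growth_rate() -> float:
    """Growth rate below which the Hockey-Stick target exceeds 0.6 k.

    Solves s*_H(r)/k = 1/r = 0.6, i.e. r = 5/3: slower-growing stocks have
    undiscounted Hockey-Stick escapement above the common B60 reference
    point (60% of unfished biomass).
    """
    return brentq(lambda r: 1.0 / r - 0.6, 1.01, 9.0,
                  xtol=1e-15, rtol=4 * np.finfo(float).eps)


def equilibrium_yield(params: GrowthParams, s) -> np.ndarray | float:
    """Sustained per-step catch ``f(s) - s`` of a constant-escapement policy.

    At the deterministic equilibrium of the harvested dynamics the stock
    returns to f(s) each season and the surplus above s is caught.
    Requires 0 <= s <= k (no surplus exists above carrying capacity).
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr > params.k):
        raise ValueError("escapement target above carrying capacity")
    out = np.asarray(growth(params, s_arr)) - s_arr
    return out if out.ndim else float(out)


def relative_yield(true_params: GrowthParams, policy_from: Model | str,
                   rho: float = 1.0) -> float:
    """Fraction of optimal equilibrium catch achieved under a wrong model.

    The manager computes the optimal escapement using ``policy_from`` with
    the same (r, k) as the true model, but the stock actually grows
    according to ``true_params``.  Returns a value in (0, 1], equal to 1
    when the policy model is the true one (or whenever the two policies
    coincide).
    """
    policy_from = Model.coerce(policy_from)
    policy_params = GrowthParams(policy_from, true_params.r, true_params.k)
    s_policy = optimal_escapement(
        EscapementProblem(policy_params, rho)).s_star
    s_true = optimal_escapement(
        EscapementProblem(true_params, rho)).s_star
    best = equilibrium_yield(true_params, s_true)
    achieved = equilibrium_yield(true_params, s_policy)
    return float(achieved / best)
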