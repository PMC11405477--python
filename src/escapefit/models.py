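"""Density-dependent growth maps for harvested populations.

Three single-equilibrium stock-recruitment models are supported, all
parameterized by the same pair (r, k):

* **Beverton-Holt** ``f_B(s) = r s / (1 + (r-1) s / k)`` — compensatory
  density dependence arising from contest competition.
* **Ricker** ``f_R(s) = s * r**(1 - s/k)`` — over-compensatory density
  dependence (scramble competition, cannibalism).  Note the growth-multiplier
  parameterization, not the ``exp(a)`` form.
* **Hockey-Stick** ``f_H(s) = min(r s, k)`` — density-independent exponential
  growth abruptly capped at carrying capacity, with a non-differentiable
  corner at ``s = k/r``.

Here ``r = f'(0)`` is the one-step growth multiplier at low density and
``k`` is the unique nonzero equilibrium (carrying capacity): ``f(k) = k``
for every model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Model",
    "GrowthParams",
    "NonDifferentiableError",
    "growth",
    "growth_derivative",
]

#: Relative half-width (in units of k) of the exclusion window around the
#: Hockey-Stick corner when evaluating the derivative.
_CORNER_RTOL = 1e-12


class Model(str, Enum):
    """Identifier for the three candidate growth models."""

    BEVERTON_HOLT = "beverton_holt"
    RICKER = "ricker"
    HOCKEY_STICK = "hockey_stick"

    @classmethod
    def coerce(cls, value: "Model | str") -> "Model":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower().replace("-", "_"))
        except ValueError:
            raise ValueError(f"unknown model {value!r}; expected one of "
                             f"{[m.value for m in cls]}") from None


class NonDifferentiableError(ValueError):
    """Raised when a derivative is requested at the Hockey-Stick corner."""


@dataclass(frozen=True)
class GrowthParams:
    """A growth model together with its (r, k) parameters.

    Parameters
    ----------
    model:
        Which of the three growth maps to use.
    r:
        Growth multiplier, the slope of the map at zero density; must
        exceed 1 for the population to be viable (and for the
        Beverton-Holt form to be well defined).
    k:
        Carrying capacity, the nonzero fixed point of the map; k > 0,
        in the same biomass units as the data.
    """

    model: Model
    r: float
    k: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model.coerce(self.model))
        r, k = float(self.r), float(self.k)
        if not (math.isfinite(r) and math.isfinite(k)):
            raise ValueError(f"non-finite growth parameters: r={r}, k={k}")
        if not r > 1.0:
            raise ValueError(f"growth multiplier must exceed 1, got r={r}")
        if not k > 0.0:
            raise ValueError(f"carrying capacity must be positive, got k={k}")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "k", k)

    @property
    def corner(self) -> float:
        """Location k/r of the Hockey-Stick kink (defined for any model)."""
        return self.k / self.r


def _validate_s(s, k: float, upper: float | None = None):
    s = np.asarray(s, dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s < 0.0):
        raise ValueError("escapement must be finite and non-negative")
    if upper is not None and np.any(s > upper):
        raise ValueError(f"escapement exceeds {upper}")
    return s


def growth(params: GrowthParams, s) -> np.ndarray | float:
    """Next-season biomass ``f(s)`` produced by escapement ``s``.

    Accepts scalars or arrays; s must be non-negative.  ``f(0) = 0``
    (extinction is absorbing) and ``f(k) = k`` for every model.
    """
    s = _validate_s(s, params.k)
    r, k = params.r, params.k
    if params.model is Model.BEVERTON_HOLT:
        out = r * s / (1.0 + (r - 1.0) * s / k)
    elif params.model is Model.RICKER:
        out = s * np.power(r, 1.0 - s / k)
    else:  # hockey stick
        out = np.minimum(r * s, k)
    return out if out.ndim else float(out)


def growth_derivative(params: GrowthParams, s) -> np.ndarray | float:
    """Slope ``f'(s)`` of the growth map.

    For the Hockey-Stick model the map has a kink at ``s = k/r``; requesting
    the derivative there raises :class:`NonDifferentiableError`.
    """
    s = _validate_s(s, params.k)
    r, k = params.r, params.k
    if params.model is Model.BEVERTON_HOLT:
        out = r / (1.0 + (r - 1.0) * s / k) ** 2
    elif params.model is Model.RICKER:
        out = np.power(r, 1.0 - s / k) * (1.0 - (s / k) * math.log(r))
    else:
        corner = params.corner
        if np.any(np.abs(s - corner) <= _CORNER_RTOL * k):
            raise NonDifferentiableError(
                f"Hockey-Stick growth is not differentiable at the corner "
                f"s = k/r = {corner}")
        out = np.where(s < corner, r, 0.0)
    return out if out.ndim else float(out)
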