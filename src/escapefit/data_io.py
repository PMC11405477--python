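"""Reading fishery biomass/catch series and the dataset-inclusion filters.

A stock assessment record is two aligned annual series: biomass ``x_t`` and
catch ``h_t``.  Escapement — the biomass left in the water after fishing —
is derived as ``e_t = x_t - h_t``; one-step transitions pair ``(e_t,
x_{t+1})`` for t = 1..T-1, which is what the growth-model likelihood
consumes.

Two filters decide whether a series is usable:

* ``filter_positive_escapement`` — drops series with any non-positive
  escapement before the final year (the log-growth of a zero or negative
  escapement is undefined).
* ``deterministic_series_score`` — an automated proxy for screening out
  model-generated (as opposed to observed) assessment output, which shows
  up as a near-noiseless functional relation between e_t and x_{t+1}.  The
  score is the R-squared of a LOWESS fit of log x_{t+1} on e_t; series
  above a configurable threshold are *flagged*, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "StockSeries",
    "FilterConfig",
    "read_series",
    "write_series",
    "filter_positive_escapement",
    "deterministic_series_score",
    "apply_filters",
]

REQUIRED_COLUMNS = ("id", "year", "biomass", "catch")


@dataclass(frozen=True)
class StockSeries:
    """One fishery's biomass and catch trajectories.

    Attributes
    ----------
    id:
        Stock identifier (free-form string).
    x:
        Biomass x_t, length T >= 2 (one transition), strictly positive.
        The default inclusion filter requires T >= 3; shorter series can
        still be represented (toy examples, truncated simulations).
    h:
        Catch h_t aligned with x.
    years:
        Assessment years (contiguous); synthetic series use 0..T-1.
    extinct:
        True when a simulated trajectory hit f(e) = 0 and was truncated.
    """

    id: str
    x: np.ndarray
    h: np.ndarray
    years: np.ndarray | None = None
    extinct: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        h = np.asarray(self.h, dtype=float)
        if x.ndim != 1 or x.shape != h.shape:
            raise ValueError("biomass and catch must be 1-D and aligned")
        if len(x) < 2:
            raise ValueError(
                f"series {self.id!r}: need at least 2 time points "
                f"(1 transition), got {len(x)}")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(h)):
            raise ValueError(f"series {self.id!r}: non-finite values")
        if np.any(x <= 0):
            raise ValueError(f"series {self.id!r}: non-positive biomass")
        years = self.years
        years = np.arange(len(x)) if years is None else np.asarray(years)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "years", years)

    @property
    def e(self) -> np.ndarray:
        """Escapement e_t = x_t - h_t."""
        return self.x - self.h

    @property
    def T(self) -> int:
        return len(self.x)

    @property
    def max_biomass(self) -> float:
        return float(self.x.max())

    @property
    def harvest_proportions(self) -> np.ndarray:
        """Observed harvest fractions h_t / x_t."""
        return self.h / self.x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.id, "year": self.years,
                             "biomass": self.x, "catch": self.h})


@dataclass(frozen=True)
class FilterConfig:
    """Dataset-inclusion settings.

    ``deterministic_r2_threshold`` flags series whose log-biomass is almost
    perfectly explained by a smooth curve in escapement — the signature of
    model-generated data.  The flag is advisory: series are only excluded
    when ``drop_deterministic`` is set.
    """

    min_length: int = 3
    deterministic_r2_threshold: float = 0.999
    drop_deterministic: bool = False
    min_transitions_for_score: int = 5


def read_series(path: str | Path) -> list[StockSeries]:
    """Read stock series from a CSV with columns id, year, biomass, catch.

    Each id becomes one :class:`StockSeries`, sorted by year.  A series is
    rejected (with a logged reason) if it has non-numeric cells, gaps in
    years, non-positive biomass, or fewer than 3 rows; the remaining series
    are returned.  An empty file yields an empty list.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("no rows in %s", path)
        return []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    out: list[StockSeries] = []
    for sid, grp in df.groupby("id", sort=True):
        try:
            grp = grp.sort_values("year")
            years = pd.to_numeric(grp["year"], errors="raise").to_numpy()
            x = pd.to_numeric(grp["biomass"], errors="raise").to_numpy(float)
            h = pd.to_numeric(grp["catch"], errors="raise").to_numpy(float)
            if np.any(np.diff(years) != 1):
                raise ValueError("years are not contiguous")
            out.append(StockSeries(id=str(sid), x=x, h=h, years=years))
        except (ValueError, TypeError) as err:
            logger.warning("rejecting series %r: %s", sid, err)
    return out


def write_series(series: list[StockSeries], path: str | Path) -> None:
    """Write series back to the CSV layout accepted by :func:`read_series`."""
    frames = [s.to_frame() for s in series]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=REQUIRED_COLUMNS))
    df.to_csv(path, index=False)


def filter_positive_escapement(series: StockSeries) -> bool:
    """Keep-flag: False iff any escapement before the final year is <= 0.

    The last escapement e_T never enters a transition, so it is ignored.
    Zero escapement is excluded together with negative: the likelihood
    needs log f(e_t), which is undefined at e_t = 0.
    """
    return bool(np.all(series.e[:-1] > 0.0))


def deterministic_series_score(series: StockSeries,
                               config: FilterConfig = FilterConfig(),
                               ) -> float | None:
    """R-squared of a LOWESS fit of log x_{t+1} on e_t.

    Near 1 means the series traces a smooth deterministic curve, the
    signature of assessment-model output rather than observations.  Returns
    None (series passes by default) when there are fewer than
    ``min_transitions_for_score`` transitions.  A series with zero variance
    in log x_{t+1} scores 1.0.
    """
    e = series.e[:-1]
    y = np.log(series.x[1:])
    if len(e) < config.min_transitions_for_score:
        return None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    # tight spans so a noise-free functional relation reaches R^2 ~ 1;
    # no robustness iterations (they down-weight curvature, not noise)
    frac = max(0.2, min(1.0, 3.0 / len(e)))
    fitted = lowess(y, e, frac=frac, it=0, return_sorted=False)
    ss_res = float(np.sum((y - fitted) ** 2))
    return max(0.0, 1.0 - ss_res / ss_tot)


def is_deterministic(series: StockSeries,
                     config: FilterConfig = FilterConfig()) -> bool:
    score = deterministic_series_score(series, config)
    return score is not None and score > config.deterministic_r2_threshold


def apply_filters(series: list[StockSeries],
                  config: FilterConfig = FilterConfig(),
                  ) -> tuple[list[StockSeries], dict[str, str]]:
    """Apply the inclusion filters; returns (kept, {id: rejection reason}).

    Filters are pure predicates on individual series, so the result is
    independent of input order and applying it twice is a no-op.
    """
    kept: list[StockSeries] = []
    rejected: dict[str, str] = {}
    for s in series:
        if s.T < config.min_length:
            rejected[s.id] = "too_short"
        elif not filter_positive_escapement(s):
            rejected[s.id] = "non_positive_escapement"
        elif config.drop_deterministic and is_deterministic(s, config):
            rejected[s.id] = "deterministic"
        else:
            if not config.drop_deterministic and is_deterministic(s, config):
                logger.info("series %r flagged as deterministic (advisory)",
                            s.id)
            kept.append(s)
    for sid, reason in rejected.items():
        logger.info("filtered out series %r: %s", sid, reason)
    return kept, rejected
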