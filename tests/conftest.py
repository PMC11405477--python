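"""Shared fixtures: small synthetic series and handmade toy data."""

import numpy as np
import pytest

from escapefit.data_io import StockSeries
from escapefit.likelihood import NoiseParams
from escapefit.models import GrowthParams, Model
from escapefit.synthetic import SimulationDesign, simulate_series


@pytest.fixture
def toy_series() -> StockSeries:
    """Tiny handmade series with positive escapement throughout."""
    return StockSeries(id="toy", x=np.array([10.0, 9.0, 11.0, 10.5]),
                       h=np.array([2.0, 1.5, 3.0, 0.0]))


@pytest.fixture
def bh_series_t200() -> StockSeries:
    """High-information Beverton-Holt series (T=200, sigma=0.05)."""
    design = SimulationDesign(
        model=Model.BEVERTON_HOLT,
        params=GrowthParams(Model.BEVERTON_HOLT, 2.0, 100.0),
        noise=NoiseParams(0.05), x0=20.0,
        harvest_pool=np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5]),
        T=200, seed=424242, id="bh-hi")
    return simulate_series(design)


def make_series(model: Model | str, r: float, k: float, sigma: float, T: int,
                seed: int, x0: float | None = None,
                pool=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5)) -> StockSeries:
    model = Model.coerce(model)
    design = SimulationDesign(
        model=model, params=GrowthParams(model, r, k),
        noise=NoiseParams(sigma), x0=x0 if x0 is not None else 0.2 * k,
        harvest_pool=np.asarray(pool, dtype=float), T=T, seed=seed,
        id=f"{model.value}-{seed}")
    return simulate_series(design)
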