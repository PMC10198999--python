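import numpy as np
import pytest

from photophen import GppSeries, PipelineConfig, make_series
from photophen.types import DailySeries


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def noisy_series():
    """Default single-season composite series at the standard noise level."""
    return make_series(seed=7)


@pytest.fixture(scope="session")
def clean_daily_logistic() -> DailySeries:
    """Already-smooth daily double-logistic curve (no noise, no sampling)."""
    from photophen.synthetic import SINGLE_SEASON, curve

    t = np.arange(1, 366)
    return DailySeries(2001, t, curve(t, SINGLE_SEASON))


@pytest.fixture(scope="session")
def parabola_series() -> GppSeries:
    """Composite series that is an exact fixed point of the smoothing chain.

    A non-negative parabola sampled daily is reproduced exactly by the
    degree-3 Savitzky-Golay filter (edges included), so the pipeline's
    smooth equals the observations and all smoothing residuals are
    exactly zero.
    """
    t = np.arange(1, 366, dtype=float)
    values = 8.0 * (1.0 - ((t - 183.0) / 182.0) ** 2)
    return GppSeries(2001, np.arange(1, 366), values, cadence=1)
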