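import numpy as np
import pandas as pd
import pytest

import hatchclim as h


@pytest.fixture(scope="session")
def default_config() -> h.GeneratorConfig:
    return h.GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def reference_pair():
    return h.reference_fits()


@pytest.fixture(scope="session")
def default_records(default_config):
    """One synthetic six-season excavation data set."""
    weather = h.gen_weather(h.gen_mei(default_config), default_config)
    return h.gen_nests(weather, default_config)


@pytest.fixture
def make_weather():
    """Factory for simple climate tables; value defaults are constant."""

    def make(years=range(2000, 2012), precip=100.0, temp=27.0, fn=None):
        rows = []
        for y in years:
            for m in range(1, 13):
                p, t = (fn(y, m) if fn else (precip, temp))
                rows.append({"year": y, "month": m, "precip_mm": p, "temp_c": t})
        return h.MonthlyClimateSeries(pd.DataFrame(rows))

    return make


@pytest.fixture
def intercept_fit():
    """Factory for an intercept-only model pinned at a given proportion."""

    def make(value, response="y"):
        return h.LinearModelFit(
            response=response, predictor_names=(), intercept=value, coefficients={}
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
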