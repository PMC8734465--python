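import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from standpp import Census, PlotWindow

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


def make_census(x, y, dbh, species=None, status=None, individual=None,
                window=None, tags=None):
    """Build a small census from parallel arrays, with sane defaults."""
    n = len(x)
    table = pd.DataFrame({
        "stem_tag": tags if tags is not None else [f"T{i:04d}" for i in range(n)],
        "individual_id": individual if individual is not None
        else [f"I{i:04d}" for i in range(n)],
        "species_code": species if species is not None else ["SP01"] * n,
        "x": np.asarray(x, float),
        "y": np.asarray(y, float),
        "dbh": np.asarray(dbh, float),
        "status": status if status is not None else ["live"] * n,
    })
    if window is None:
        window = PlotWindow(500.0, 700.0)
    return Census(window, table)


@pytest.fixture
def small_window():
    return PlotWindow(100.0, 100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_census(rng):
    """200 stems of 3 species scattered over the 35-ha window."""
    n = 200
    return make_census(
        x=rng.uniform(0, 500, n), y=rng.uniform(0, 700, n),
        dbh=np.round(rng.lognormal(np.log(8), 0.5, n), 1) + 1.0,
        species=rng.choice(["SP01", "SP02", "SP03"], n))
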