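import numpy as np
import pandas as pd
import pytest

import cpiswitch as cs

# fixture simulations use one a-priori root seed (the tax year)
ROOT_SEED = 2014


@pytest.fixture(scope="session")
def refrescos() -> cs.ModelParams:
    return cs.preset("refrescos")


@pytest.fixture(scope="session")
def pan_dulce() -> cs.ModelParams:
    return cs.preset("pan_dulce")


@pytest.fixture
def short_inflation(refrescos) -> cs.InflationSeries:
    cfg = cs.SimulationConfig(params=refrescos, n_months=10, seed=ROOT_SEED)
    return cs.simulate_inflation(cfg)


def write_cpi_csv(path, months, values, date_column="date", value_column="value"):
    """Write a minimal monthly index CSV for reader tests."""
    pd.DataFrame({date_column: months, value_column: values}).to_csv(path, index=False)
    return path


def month_range(start: str, n: int) -> list[str]:
    return [str(p) for p in pd.period_range(start, periods=n, freq="M")]


def random_params(rng: np.random.Generator, ar_order: int = 0) -> cs.ModelParams:
    """A valid, reasonably well-conditioned random parameter draw."""
    mu = np.sort(rng.normal(0.05, 0.06, size=2))
    mu[1] = mu[0] + max(mu[1] - mu[0], 0.01)
    return cs.ModelParams(
        p11=rng.uniform(0.05, 0.98),
        p22=rng.uniform(0.05, 0.98),
        mu=(float(mu[0]), float(mu[1])),
        sigma=(float(rng.uniform(0.005, 0.1)), float(rng.uniform(0.005, 0.1))),
        phi=tuple(rng.uniform(-0.5, 0.5, size=ar_order)),
    )
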