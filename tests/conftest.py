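"""Shared fixtures: printed micro-fixtures and hypothesis configuration."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cheprobit import DesignMatrices

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# 20 printed households: varied weights, sizes, budgets, food shares and OOP
# spending, including one zero-OOP household and one catastrophic-by-a-mile
# household.  Currency is arbitrary (annual).
HOUSEHOLDS_20_CSV = """\
household_id,weight,total_exp,food_exp,oop,hh_size
1,1.0,12000,6500,300,4
2,0.5,8000,4800,0,2
3,2.0,25000,9000,1500,5
4,1.5,15000,7400,4200,6
5,1.0,42000,12000,900,3
6,3.0,9500,5600,2600,7
7,1.0,18000,8100,650,4
8,0.8,60000,15000,9000,2
9,1.2,11000,6200,450,5
10,2.5,14000,7100,1900,3
11,1.0,30000,10500,120,6
12,0.6,22000,8900,3300,8
13,1.0,9800,5900,780,1
14,1.8,16500,7700,2100,4
15,1.0,27000,9800,60,2
16,0.9,13500,6900,5100,5
17,2.2,35000,11200,1400,6
18,1.0,10500,6000,950,3
19,1.4,48000,13500,700,7
20,1.0,20000,8600,2800,4
"""


@pytest.fixture(scope="session")
def households20() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(HOUSEHOLDS_20_CSV))


# 8 printed observations for the grid-search oracle: intercept-only mean
# equation, one variance covariate, non-uniform weights; the optimum is
# interior in [-3, 3]^2.
TOY8_X = np.array([-1.5, -1.0, -0.5, -0.2, 0.2, 0.5, 1.0, 1.5])
TOY8_C = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0])
TOY8_W = np.array([1.0, 2.0, 1.0, 1.0, 1.0, 1.0, 2.0, 1.0])


@pytest.fixture(scope="session")
def toy8_design() -> DesignMatrices:
    return DesignMatrices(
        Y=np.ones((8, 1)),
        X=TOY8_X[:, None],
        c=TOY8_C.copy(),
        w=TOY8_W.copy(),
        mean_names=("intercept",),
        var_names=("x",),
    )


def make_design(Y, X, c, w, mean_names=None, var_names=None) -> DesignMatrices:
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    k, m = Y.shape[1], X.shape[1]
    return DesignMatrices(
        Y=Y,
        X=X,
        c=np.asarray(c, float),
        w=np.asarray(w, float),
        mean_names=tuple(mean_names or ["intercept"] + [f"y{j}" for j in range(1, k)]),
        var_names=tuple(var_names or [f"x{j}" for j in range(m)]),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
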