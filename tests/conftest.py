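import numpy as np
import pandas as pd
import pytest

from psadjust import (
    PropensitySpec,
    ScenarioConfig,
    combine,
    draw_convenience,
    generate_population,
    internet_population,
    run_scenario,
    srswor,
)

COVARIATES = ["age", "gender", "nationality", "education"]


@pytest.fixture(scope="session")
def pop50k():
    """One realisation of the full 50,000-person voter population."""
    return generate_population(50_000, 101)


@pytest.fixture(scope="session")
def mini_pop():
    return generate_population(2000, 11)


@pytest.fixture(scope="session")
def mid_sample(mini_pop):
    """A moderate combined sample (200 volunteer + 100 reference units)."""
    net = internet_population(mini_pop)
    ref = srswor(mini_pop, 100, 5)
    vol = draw_convenience(net, "logit_linear", 200, 6)
    return combine(ref, vol, COVARIATES)


@pytest.fixture(scope="session")
def mc_result(pop50k):
    """Scaled-down Monte-Carlo study: SRSWOR volunteers, logistic PSA,
    Hajek weights, 200 replications at n_vs = 2000, n_rs = 500."""
    config = ScenarioConfig(
        scheme="srswor",
        n_vs=2000,
        n_rs=500,
        reps=200,
        estimators=[PropensitySpec("logistic")],
        weighting="hajek",
        master_seed=7,
    )
    return run_scenario(config, population=pop50k)


def make_binary_sample(n00, n01, n10, n11):
    """Combined sample with one binary covariate from the four cell counts
    (z, x): (0,0), (0,1), (1,0), (1,1). Reference rows first."""
    from psadjust import DrawnSample

    x_ref = ["0"] * n00 + ["1"] * n01
    x_vol = ["0"] * n10 + ["1"] * n11
    ref = DrawnSample(pd.DataFrame({"x": x_ref}), np.ones(len(x_ref)), "reference")
    vol = DrawnSample(pd.DataFrame({"x": x_vol}), np.ones(len(x_vol)), "volunteer")
    return combine(ref, vol, ["x"])
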