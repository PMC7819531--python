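import numpy as np
import pandas as pd
import pytest

from ivdid import (
    RunConfig,
    ScenarioParams,
    StudyWindow,
    WeeklySeries,
    analyze_scenario,
    generate_scenario,
)


@pytest.fixture
def window() -> StudyWindow:
    return StudyWindow("2019-12-18", "2020-04-15", "2020-03-12")


@pytest.fixture
def weekly_constant() -> WeeklySeries:
    return WeeklySeries(
        pd.date_range("2020-01-01", periods=3, freq="7D"), [70.0, 70.0, 70.0]
    )


def make_random_panel(rng: np.random.Generator, n_days: int = 40,
                      beta: float = -0.05, strong: float = 30.0) -> pd.DataFrame:
    """Small random two-period panel with a genuine first stage.

    x responds to the instrument with step ``strong``; y is beta * x plus
    covariate terms and noise.
    """
    cut = n_days // 2
    rows = []
    for period in (0, 1):
        t = np.arange(n_days)
        z = ((period == 1) & (t >= cut)).astype(int)
        x = (
            100.0
            + 5.0 * period
            + 0.5 * t
            - 0.01 * t**2
            - strong * z
            + rng.normal(0, 2.0, n_days)
        )
        y = (
            beta * x
            + 3.0 * period
            + 0.2 * t
            + 0.001 * t**2
            - 1e-5 * t**3
            + rng.normal(0, 1.0, n_days)
        )
        rows.append(
            pd.DataFrame(
                {
                    "date": pd.date_range("2020-01-01", periods=n_days),
                    "period": period,
                    "t": t,
                    "t2": t**2,
                    "t3": t**3,
                    "z": z,
                    "x": x,
                    "y": y,
                }
            )
        )
    panel = pd.concat(rows, ignore_index=True)
    panel.attrs["lag"] = 0
    return panel


@pytest.fixture
def random_panel() -> pd.DataFrame:
    return make_random_panel(np.random.default_rng(7))


@pytest.fixture(scope="session")
def noiseless_lag0_result():
    """Full-pipeline analysis of the noiseless default scenario, lag 0."""
    params = ScenarioParams(noise="none", true_lag=0)
    return analyze_scenario(generate_scenario(params)), params
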