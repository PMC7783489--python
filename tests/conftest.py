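import numpy as np
import pandas as pd
import pytest

from virtualcontrols import (
    Cohort,
    CovariateSchema,
    OutcomeSpec,
    PrognosticRegression,
    SimulationScenario,
    Variable,
    generate_single_arm_cohort,
    generate_training_cohort,
)


@pytest.fixture
def default_scenario():
    """The package's default study conditions (R^2 = 0.6, no bias mechanisms)."""
    return SimulationScenario()


@pytest.fixture
def small_scenario():
    """Down-sized cohorts for fast unit tests."""
    return SimulationScenario(n_train=200, n_treated=60, n_rct_per_arm=60)


@pytest.fixture
def training_cohort(small_scenario):
    return generate_training_cohort(small_scenario, seed=11)


@pytest.fixture
def fitted(training_cohort):
    return PrognosticRegression(training_cohort).fit()


@pytest.fixture
def treated_arm(small_scenario):
    return generate_single_arm_cohort(small_scenario, seed=12)


def make_continuous_cohort(x, y, treated=0, ids=None, extra_covariates=None):
    """Hand-built single-covariate cohort used across unit tests."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    data = {"id": ids or [f"s{i}" for i in range(n)], "x1": x}
    variables = [Variable("x1")]
    if extra_covariates:
        for name, col in extra_covariates.items():
            data[name] = np.asarray(col, dtype=float)
            variables.append(Variable(name))
    data["treated"] = np.full(n, treated)
    data["y"] = np.asarray(y, dtype=float)
    schema = CovariateSchema(tuple(variables))
    return Cohort(pd.DataFrame(data), schema, OutcomeSpec("y", "continuous"))


@pytest.fixture
def simple_cohort():
    rng = np.random.default_rng(5)
    x = rng.normal(size=50)
    y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 50)
    return make_continuous_cohort(x, y)
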