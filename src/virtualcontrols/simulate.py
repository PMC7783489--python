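"""Synthetic cohorts with the structure virtual controls assume — and the
biases that threaten them.

The generative law is a linear model on independent (optionally
exchangeably correlated) standard-normal covariates, plus optional binary
covariates, a hidden standard-normal confounder ``u`` (the "motivation for
improvement" analogue — it moves the outcome but is never exposed as a
covariate), and Gaussian residual noise::

    y = intercept + x . beta + b . beta_binary + gamma * u + eps,
    eps ~ Normal(0, sigma)          (continuous outcome)
    y ~ Bernoulli(expit(same linear predictor))   (binary outcome)

Treated subjects receive an additive effect ``tau`` (log-odds shift for
binary outcomes).  Three enrolment mechanisms are modelled:

* training cohorts — untreated, no selection;
* single-arm cohorts — subjects opt in with probability uniform
  (``selection='none'``), logistic in an *observed* covariate, or logistic
  in the *hidden* confounder (classic self-selection bias);
* randomized cohorts — 1:1 assignment with a stated fraction preferring
  treatment; subjects randomized against their preference receive a
  demoralization penalty on their outcome (additive, or log-odds for
  binary), degrading the unblinded RCT.

The true prognostic R-square is available in closed form,
``Var(x.beta) / (Var(x.beta) + gamma^2 + sigma^2)``, so scenarios can be
parameterised by target R-square; the expected bias of the virtual-control
estimator under hidden selection is computed by deterministic quadrature.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import integrate, stats
from scipy.special import expit

from .cohort import Cohort, CovariateSchema, OutcomeSpec, Variable
from .exceptions import AccrualError, ConfigurationError

ACCRUAL_FACTOR = 100  # candidate draws allowed per accrued subject


@dataclass(frozen=True)
class SimulationScenario:
    """Generative truth for one simulated study condition.

    Defaults describe a moderately prognostic setting: three continuous
    predictors with coefficients (0.5, 0.4, 0.3) and residual s.d. 0.5774,
    giving true prognostic R-square 0.60; no treatment effect, no hidden
    confounding, no selection, balanced preference, no demoralization;
    500 untreated training subjects and 100 treated subjects (100 per arm
    when randomized).
    """

    p: int = 3
    beta: tuple[float, ...] = (0.5, 0.4, 0.3)
    intercept: float = 0.0
    sigma: float = 0.5774
    tau: float = 0.0
    gamma: float = 0.0
    selection: str = "none"  # none | observed | hidden
    selection_strength: float = 1.0
    selection_offset: float = 0.0  # log-odds of baseline opt-in
    preference: float = 0.5
    demoralization: float = 0.0
    n_train: int = 500
    n_treated: int = 100
    n_rct_per_arm: int = 100
    outcome_scale: str = "continuous"  # continuous | binary
    rho: float = 0.0  # exchangeable correlation among continuous covariates
    binary_prevalence: tuple[float, ...] = ()
    binary_beta: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if not (0 <= self.preference <= 1):
            raise ConfigurationError("preference must lie in [0, 1]")
        if min(self.n_train, self.n_treated, self.n_rct_per_arm) < 1:
            raise ConfigurationError("cohort sizes must be >= 1")
        if len(self.beta) != self.p:
            raise ConfigurationError(f"beta has {len(self.beta)} entries but p={self.p}")
        if len(self.binary_prevalence) != len(self.binary_beta):
            raise ConfigurationError("binary_prevalence and binary_beta lengths differ")
        if any(not (0 < q < 1) for q in self.binary_prevalence):
            raise ConfigurationError("binary prevalences must lie in (0, 1)")
        if self.selection not in ("none", "observed", "hidden"):
            raise ConfigurationError(f"unknown selection mode {self.selection!r}")
        if not (-1 / max(self.p - 1, 1) < self.rho < 1):
            raise ConfigurationError("rho outside the exchangeable-correlation range")
        if self.outcome_scale not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown outcome scale {self.outcome_scale!r}")

    # -- closed-form quantities -----------------------------------------
    @property
    def linear_predictor_variance(self) -> float:
        """Var(x.beta + b.beta_binary) under the covariate law."""
        b = np.asarray(self.beta)
        sigma_x = np.full((self.p, self.p), self.rho)
        np.fill_diagonal(sigma_x, 1.0)
        v = float(b @ sigma_x @ b) if self.p else 0.0
        for q, bb in zip(self.binary_prevalence, self.binary_beta):
            v += bb**2 * q * (1 - q)
        return v

    @property
    def true_r2(self) -> float:
        """Prognostic R-square of the best covariate-based predictor."""
        v = self.linear_predictor_variance
        return v / (v + self.gamma**2 + self.sigma**2)

    def sigma_for_r2(self, r2: float) -> float:
        """Residual s.d. that yields target R-square under this beta/gamma."""
        if not (0 < r2 < 1):
            raise ConfigurationError(f"target R-square must be in (0,1), got {r2}")
        v = self.linear_predictor_variance
        s2 = v * (1 - r2) / r2 - self.gamma**2
        if s2 <= 0:
            raise ConfigurationError(
                f"R-square {r2} infeasible: hidden-confounder variance "
                f"{self.gamma**2:.4g} already exceeds the required noise budget"
            )
        return float(np.sqrt(s2))

    def with_r2(self, r2: float) -> "SimulationScenario":
        return replace(self, sigma=self.sigma_for_r2(r2))

    @property
    def outcome_sd(self) -> float:
        """Total s.d. of the untreated continuous outcome."""
        return float(
            np.sqrt(self.linear_predictor_variance + self.gamma**2 + self.sigma**2)
        )

    # -- schema / serialization ----------------------------------------
    def covariate_names(self) -> list[str]:
        return [f"x{i+1}" for i in range(self.p)] + [
            f"b{i+1}" for i in range(len(self.binary_prevalence))
        ]

    def schema(self) -> CovariateSchema:
        vs = [Variable(f"x{i+1}", "continuous") for i in range(self.p)]
        vs += [Variable(f"b{i+1}", "binary") for i in range(len(self.binary_prevalence))]
        return CovariateSchema(tuple(vs))

    def outcome_spec(self) -> OutcomeSpec:
        return OutcomeSpec("y", self.outcome_scale)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        for key in ("beta", "binary_prevalence", "binary_beta"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ConfigurationError(f"bad scenario file {path}: {exc}") from exc


@dataclass(frozen=True)
class GroundTruth:
    """What the scenario implies the estimator should recover."""

    tau: float
    true_r2: float
    expected_bias: float

    @classmethod
    def from_scenario(cls, scenario: SimulationScenario) -> "GroundTruth":
        return cls(
            tau=scenario.tau,
            true_r2=scenario.true_r2,
            expected_bias=expected_selection_bias(scenario),
        )


def expected_hidden_u_given_optin(strength: float, offset: float = 0.0) -> float:
    """E[u | opt-in] when opt-in probability is expit(offset + strength*u),
    u ~ N(0,1); evaluated by deterministic quadrature
    E[u * expit(.)] / E[expit(.)] (the denominator is exactly 1/2 when the
    offset is zero, by symmetry)."""
    num, _ = integrate.quad(
        lambda u: u * expit(offset + strength * u) * stats.norm.pdf(u),
        -12, 12, limit=200,
    )
    if offset == 0.0:
        return 2.0 * num
    den, _ = integrate.quad(
        lambda u: expit(offset + strength * u) * stats.norm.pdf(u), -12, 12, limit=200
    )
    return num / den


def expected_selection_bias(scenario: SimulationScenario) -> float:
    """Expected bias of the virtual-control mean-added-value estimator.

    Zero under no selection or selection on an observed covariate (the
    model adjusts for what it measures); under hidden selection the treated
    group's mean confounder value is shifted, and the bias is
    ``gamma * E[u | opt-in]``.
    """
    if scenario.selection != "hidden" or scenario.gamma == 0:
        return 0.0
    return scenario.gamma * expected_hidden_u_given_optin(
        scenario.selection_strength, scenario.selection_offset
    )


# ---------------------------------------------------------------------------
# generators


def _draw_covariates(scenario: SimulationScenario, n: int, rng) -> np.ndarray:
    if scenario.rho == 0:
        x = rng.standard_normal((n, scenario.p))
    else:
        r = scenario.rho
        common = rng.standard_normal((n, 1))
        x = np.sqrt(r) * common + np.sqrt(1 - r) * rng.standard_normal((n, scenario.p))
    return x


def _base_draw(scenario: SimulationScenario, n: int, rng):
    """Covariates, binary covariates, hidden confounder and linear predictor."""
    x = _draw_covariates(scenario, n, rng)
    b = np.column_stack(
        [rng.random(n) < q for q in scenario.binary_prevalence]
    ).astype(float) if scenario.binary_prevalence else np.empty((n, 0))
    u = rng.standard_normal(n)
    lp = scenario.intercept + x @ np.asarray(scenario.beta) + u * scenario.gamma
    if scenario.binary_prevalence:
        lp = lp + b @ np.asarray(scenario.binary_beta)
    return x, b, u, lp


def _outcomes(scenario: SimulationScenario, lp: np.ndarray, shift: np.ndarray, rng):
    """Realise outcomes from linear predictor + treatment/penalty shift."""
    if scenario.outcome_scale == "continuous":
        return lp + shift + rng.normal(0, scenario.sigma, len(lp))
    return (rng.random(len(lp)) < expit(lp + shift)).astype(float)


def _assemble(scenario, ids, x, b, u, y, treated, extra=None) -> Cohort:
    data = {"id": ids}
    for j in range(scenario.p):
        data[f"x{j+1}"] = x[:, j]
    for j in range(len(scenario.binary_prevalence)):
        data[f"b{j+1}"] = b[:, j]
    data["treated"] = treated
    data["y"] = y
    df = pd.DataFrame(data)
    df["_hidden_u"] = u  # generative bookkeeping; not a covariate
    if extra:
        for k, v in extra.items():
            df[k] = v
    return Cohort(df, scenario.schema(), scenario.outcome_spec())


def generate_training_cohort(scenario: SimulationScenario, seed: int | None = None) -> Cohort:
    """Untreated cohort for prognostic-model training (no selection)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_train
    x, b, u, lp = _base_draw(scenario, n, rng)
    y = _outcomes(scenario, lp, np.zeros(n), rng)
    ids = [f"t{i}" for i in range(n)]
    return _assemble(scenario, ids, x, b, u, y, np.zeros(n, dtype=int))


def generate_single_arm_cohort(scenario: SimulationScenario, seed: int | None = None) -> Cohort:
    """Treated single-arm cohort accrued under the scenario's selection mode.

    Candidates opt in with probability 1 (``none``),
    expit(offset + strength * x1) (``observed``), or
    expit(offset + strength * u) (``hidden``); treated outcomes include
    ``tau``.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    target = scenario.n_treated
    rows_x, rows_b, rows_u, rows_lp = [], [], [], []
    accrued = 0
    drawn = 0
    batch = max(64, 2 * target)
    while accrued < target:
        if drawn >= ACCRUAL_FACTOR * target:
            raise AccrualError(
                f"accrued only {accrued}/{target} subjects after {drawn} draws; "
                "selection too extreme"
            )
        m = min(batch, ACCRUAL_FACTOR * target - drawn)
        x, b, u, lp = _base_draw(scenario, m, rng)
        drawn += m
        off = scenario.selection_offset
        if scenario.selection == "none":
            accept = np.ones(m, dtype=bool)
        elif scenario.selection == "observed":
            accept = rng.random(m) < expit(off + scenario.selection_strength * x[:, 0])
        else:
            accept = rng.random(m) < expit(off + scenario.selection_strength * u)
        rows_x.append(x[accept])
        rows_b.append(b[accept])
        rows_u.append(u[accept])
        rows_lp.append(lp[accept])
        accrued += int(accept.sum())
    x = np.concatenate(rows_x)[:target]
    b = np.concatenate(rows_b)[:target]
    u = np.concatenate(rows_u)[:target]
    lp = np.concatenate(rows_lp)[:target]
    shift = np.full(target, float(scenario.tau))
    y = _outcomes(scenario, lp, shift, rng)
    ids = [f"a{i}" for i in range(target)]
    return _assemble(scenario, ids, x, b, u, y, np.ones(target, dtype=int))


def generate_rct_cohort(scenario: SimulationScenario, seed: int | None = None) -> Cohort:
    """Two randomized arms with preference and satisfaction bookkeeping.

    A fraction ``preference`` of participants prefer treatment; assignment
    is 1:1 regardless.  Participants assigned against their preference
    receive the demoralization penalty (subtracted from the continuous
    outcome; subtracted on the log-odds scale for binary outcomes).
    Extra columns: ``prefers_treatment``, ``satisfied``.
    """
    rng = np.random.default_rng(scenario.seed + 2 if seed is None else seed)
    n = 2 * scenario.n_rct_per_arm
    x, b, u, lp = _base_draw(scenario, n, rng)
    prefers = (rng.random(n) < scenario.preference).astype(int)
    assign = np.zeros(n, dtype=int)
    assign[rng.permutation(n)[: scenario.n_rct_per_arm]] = 1
    satisfied = (assign == prefers).astype(int)
    shift = scenario.tau * assign - scenario.demoralization * (1 - satisfied)
    y = _outcomes(scenario, lp, shift, rng)
    ids = [f"r{i}" for i in range(n)]
    return _assemble(
        scenario,
        ids,
        x,
        b,
        u,
        y,
        assign,
        extra={"prefers_treatment": prefers, "satisfied": satisfied},
    )
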