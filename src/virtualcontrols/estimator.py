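"""Virtual-control generation and single-arm effect estimation.

Given a prognostic model fitted to untreated subjects and a treated
single-arm cohort, each treated subject's model prediction is their
*virtual control* — the estimated counterfactual outcome without the
intervention.  The treatment effect is then estimated by comparing observed
outcomes with the virtual controls:

* continuous outcomes — per-subject *added-value scores* (observed minus
  predicted); the mean score estimates the additive effect, the mean/SD
  ratio is the standardized effect size, and a t construction gives the CI
  and test;
* binary outcomes — the risk difference between the observed event
  proportion and the mean predicted probability, tested against the
  Poisson-binomial null implied by the per-subject predicted probabilities
  (exact for small n, normal approximation otherwise).

Uncertainty modes: ``plugin`` treats predictions as fixed;
``analytic-propagated`` (default when the coefficient covariance is stored
with the model) adds the propagated training-coefficient uncertainty to the
standard error; ``bootstrap-propagated`` refits the prognostic model on
resampled training data and takes percentile intervals over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, PrognosticModel, design_matrix
from .exceptions import (
    AlignmentError,
    ContractError,
    ConvergenceError,
    InsufficientDataError,
)
from .prognostic import (
    PrognosticRegression,
    PrognosticResults,
    predicted_outcome,
    truncation_flags,
)

EXACT_TEST_MAX_N = 20  # Poisson-binomial null evaluated exactly up to here
DEFAULT_LEVEL = 0.95


@dataclass(frozen=True)
class VirtualControlSet:
    """Per-subject counterfactual predictions for a treated cohort.

    ``table`` columns: ``id``, ``prediction`` (value for the linear family,
    event probability for logistic), ``extrapolation`` (any covariate
    outside the model's training support).  Subjects skipped for missing
    covariates are listed in ``skipped_ids``.
    """

    table: pd.DataFrame
    family: str
    model_version: int
    skipped_ids: tuple[str, ...] = ()

    @property
    def predictions(self) -> pd.Series:
        return self.table.set_index("id")["prediction"]

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_extrapolated(self) -> int:
        return int(self.table["extrapolation"].sum())


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate, CI and test for the intervention effect.

    ``measure`` is one of ``mean-added-value``, ``risk-difference``.
    ``standardized`` (continuous only) is mean/SD of the added-value
    scores; ``risk_ratio`` (binary only) is observed rate / mean predicted
    rate.  ``extras`` carries secondary intervals (e.g. the bootstrap CI of
    the binary estimator) and bookkeeping counts.
    """

    measure: str
    point: float
    ci: tuple[float, float]
    level: float
    statistic: float
    pvalue: float
    method: str
    n: int
    uncertainty_mode: str
    standardized: float | None = None
    risk_ratio: float | None = None
    n_extrapolated: int = 0
    n_skipped: int = 0
    model_version: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.level < 1):
            raise ContractError(f"confidence level must be in (0,1), got {self.level}")

    def summary(self) -> str:
        lo, hi = self.ci
        lines = [
            f"Effect estimate ({self.measure}, n={self.n})",
            f"  point:     {self.point:.4f}",
            f"  {int(self.level*100)}% CI:    ({lo:.4f}, {hi:.4f})   [{self.uncertainty_mode}]",
            f"  test:      statistic={self.statistic:.4f}, p={self.pvalue:.4g} ({self.method})",
        ]
        if self.standardized is not None:
            lines.append(f"  standardized effect size: {self.standardized:.4f}")
        if self.risk_ratio is not None:
            lines.append(f"  risk ratio: {self.risk_ratio:.4f}")
        if self.n_extrapolated:
            lines.append(f"  subjects with extrapolated predictions: {self.n_extrapolated}")
        if self.n_skipped:
            lines.append(f"  subjects skipped (missing covariates): {self.n_skipped}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "measure": self.measure,
            "point": self.point,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "level": self.level,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "method": self.method,
            "n": self.n,
            "uncertainty_mode": self.uncertainty_mode,
            "standardized": self.standardized,
            "risk_ratio": self.risk_ratio,
            "n_extrapolated": self.n_extrapolated,
            "n_skipped": self.n_skipped,
            "model_version": self.model_version,
            "seed": self.seed,
        }
        d.update(self.extras)
        return d


# ---------------------------------------------------------------------------
# prediction


def predict_virtual_controls(model: PrognosticModel, treated: Cohort) -> VirtualControlSet:
    """Plug each treated subject's covariates into the coefficient set."""
    if not treated.all_treated():
        raise ContractError("virtual controls are generated for treated subjects only")
    if set(treated.schema.names) != set(model.schema.names):
        raise ContractError(
            f"cohort covariates {sorted(treated.schema.names)} do not match "
            f"model schema {sorted(model.schema.names)}"
        )
    pred, mask = predicted_outcome(model, treated)
    skipped = tuple(treated.ids[~mask])
    if skipped:
        warnings.warn(
            f"{len(skipped)} subject(s) skipped for missing covariates: "
            f"{list(skipped)[:5]}...",
            stacklevel=2,
        )
    flags = truncation_flags(model, treated).any(axis=1)
    table = pd.DataFrame(
        {
            "id": treated.ids[mask].to_numpy(),
            "prediction": pred[mask.to_numpy()],
            "extrapolation": flags[mask].to_numpy(),
        }
    )
    return VirtualControlSet(
        table=table,
        family=model.family,
        model_version=model.version,
        skipped_ids=skipped,
    )


def added_value_scores(treated: Cohort, vc: VirtualControlSet) -> pd.Series:
    """Observed minus predicted outcome per subject, indexed by id."""
    if treated.outcome_spec.scale != "continuous":
        raise ContractError("added-value scores require a continuous outcome")
    obs = pd.Series(
        pd.to_numeric(treated.outcome, errors="coerce").to_numpy(),
        index=treated.ids.to_numpy(),
    )
    pred = vc.predictions
    missing = pred.index.difference(obs.index)
    if len(missing):
        raise AlignmentError(f"virtual-control ids not in cohort: {list(missing)[:5]}")
    scores = obs.loc[pred.index] - pred
    scores.name = "added_value"
    return scores


# ---------------------------------------------------------------------------
# continuous-outcome estimation


def _mean_design_vector(model: PrognosticModel, treated: Cohort, ids) -> np.ndarray:
    X, names, _ = design_matrix(treated, model.schema)
    keep = treated.ids.isin(ids).to_numpy()
    xbar = np.nanmean(X[keep], axis=0) if keep.any() else np.zeros(len(names))
    order = list(model.training_meta.param_order or ["(intercept)"] + names)
    vec = np.zeros(len(order))
    for j, nm in enumerate(order):
        if nm == "(intercept)":
            vec[j] = 1.0
        else:
            vec[j] = xbar[names.index(nm)]
    return vec


def estimate_effect_continuous(
    treated: Cohort,
    vc: VirtualControlSet,
    level: float = DEFAULT_LEVEL,
    model: PrognosticModel | None = None,
    uncertainty: str = "auto",
) -> EffectEstimate:
    """Mean added-value score with t-based CI and test against zero.

    With ``uncertainty='auto'`` (default) and a model artifact carrying its
    coefficient covariance, the standard error adds the propagated variance
    of the mean prediction (a quadratic form of the mean covariate vector
    in the training covariance); this keeps the test close to its nominal
    level when the prognostic model is itself estimated.  ``'plugin'``
    treats the predictions as fixed constants.
    """
    scores = added_value_scores(treated, vc).to_numpy(dtype=float)
    n = len(scores)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 subjects, got {n}")
    point = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))

    cov = model.training_meta.cov_matrix() if model is not None else None
    mode = uncertainty
    if mode == "auto":
        mode = "analytic-propagated" if cov is not None else "plugin"
    if mode == "analytic-propagated" and cov is None:
        raise ContractError("analytic propagation requires a model with cov_params")

    if sd == 0.0 and mode == "plugin":
        p = 1.0 if point == 0.0 else 0.0
        return EffectEstimate(
            measure="mean-added-value",
            point=point,
            ci=(point, point),
            level=level,
            statistic=float("nan"),
            pvalue=p,
            method="degenerate-zero-variance",
            n=n,
            uncertainty_mode="plugin",
            standardized=None,
            n_extrapolated=vc.n_extrapolated,
            n_skipped=len(vc.skipped_ids),
            model_version=vc.model_version,
        )

    var_mean = sd**2 / n
    if mode == "analytic-propagated":
        a = _mean_design_vector(model, treated, vc.predictions.index)
        var_mean += float(a @ cov @ a)
    se = float(np.sqrt(var_mean))
    dof = n - 1
    tcrit = stats.t.ppf(0.5 + level / 2, dof)
    tstat = point / se if se > 0 else float("inf") * np.sign(point)
    pval = float(2 * stats.t.sf(abs(tstat), dof)) if np.isfinite(tstat) else 0.0
    return EffectEstimate(
        measure="mean-added-value",
        point=point,
        ci=(point - tcrit * se, point + tcrit * se),
        level=level,
        statistic=float(tstat),
        pvalue=pval,
        method="one-sample-t" if mode == "plugin" else "one-sample-t-propagated",
        n=n,
        uncertainty_mode=mode,
        standardized=point / sd if sd > 0 else None,
        n_extrapolated=vc.n_extrapolated,
        n_skipped=len(vc.skipped_ids),
        model_version=vc.model_version,
    )


# ---------------------------------------------------------------------------
# binary-outcome estimation: Poisson-binomial null


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by convolution."""
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ContractError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1 - p, p])
    return pmf


def poisson_binomial_test(k: int, probs: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided test of observed count k against sum of Bernoulli(p_i).

    Exact tail evaluation (2*min tail, capped at 1) for n <= 20; otherwise
    the normal approximation with mean sum(p) and variance sum(p(1-p)).
    Returns (statistic, p-value, method tag); the statistic is the exact
    lower-tail probability's count for the exact branch and the z value for
    the normal branch.
    """
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    mu = float(np.sum(probs))
    var = float(np.sum(probs * (1 - probs)))
    if n <= EXACT_TEST_MAX_N:
        pmf = poisson_binomial_pmf(probs)
        lower = float(pmf[: k + 1].sum())
        upper = float(pmf[k:].sum())
        p = min(1.0, 2 * min(lower, upper))
        z = (k - mu) / np.sqrt(var) if var > 0 else float("nan")
        return z, p, "poisson-binomial-exact"
    if var == 0:
        return float("nan"), 1.0 if k == round(mu) else 0.0, "degenerate"
    z = (k - mu) / np.sqrt(var)
    # continuity-corrected two-sided tail
    zc = max(abs(k - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(z), float(min(1.0, 2 * stats.norm.sf(zc))), "poisson-binomial-normal"


def estimate_effect_binary(
    treated: Cohort,
    vc: VirtualControlSet,
    level: float = DEFAULT_LEVEL,
    bootstrap: int = 0,
    seed: int | None = None,
) -> EffectEstimate:
    """Risk difference: observed event proportion minus mean predicted
    probability, with the Poisson-binomial test of the observed event count
    against the sum of predicted probabilities.

    The primary CI is the normal approximation on the risk difference
    (predictions fixed); if ``bootstrap`` > 0, a subject-resampling
    percentile CI is reported alongside in ``extras['ci_bootstrap']``.
    """
    if treated.outcome_spec.scale != "binary":
        raise ContractError("binary estimator requires a binary outcome")
    probs = vc.predictions
    if ((probs < 0) | (probs > 1)).any():
        raise ContractError("virtual-control probabilities must lie in [0, 1]")
    obs = pd.Series(
        treated.outcome.to_numpy(dtype=float), index=treated.ids.to_numpy()
    ).loc[probs.index]
    n = len(obs)
    if n < 1:
        raise InsufficientDataError("no usable subjects")
    k = int(obs.sum())
    p_obs = k / n
    p_pred = float(probs.mean())
    point = p_obs - p_pred
    rr = p_obs / p_pred if p_pred > 0 else float("inf")
    z, pval, method = poisson_binomial_test(k, probs.to_numpy())
    se = np.sqrt(p_obs * (1 - p_obs) / n)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    extras: dict = {"observed_rate": p_obs, "mean_predicted_rate": p_pred}
    if bootstrap:
        rng = np.random.default_rng(seed)
        reps = np.empty(bootstrap)
        o = obs.to_numpy()
        pr = probs.to_numpy()
        for b in range(bootstrap):
            idx = rng.integers(0, n, n)
            reps[b] = o[idx].mean() - pr[idx].mean()
        alpha = 1 - level
        extras["ci_bootstrap"] = (
            float(np.quantile(reps, alpha / 2)),
            float(np.quantile(reps, 1 - alpha / 2)),
        )
    return EffectEstimate(
        measure="risk-difference",
        point=point,
        ci=(point - zcrit * se, point + zcrit * se),
        level=level,
        statistic=z,
        pvalue=pval,
        method=method,
        n=n,
        uncertainty_mode="plugin",
        risk_ratio=rr,
        n_extrapolated=vc.n_extrapolated,
        n_skipped=len(vc.skipped_ids),
        model_version=vc.model_version,
        seed=seed,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# bootstrap propagation of training-model uncertainty


def bootstrap_propagate(
    training: Cohort,
    treated: Cohort,
    B: int = 500,
    seed: int | None = None,
    level: float = DEFAULT_LEVEL,
) -> EffectEstimate:
    """Resample both cohorts, refit, re-predict and re-estimate.

    Each replicate resamples the training cohort (propagating prognostic-
    coefficient uncertainty through a refit) and the treated cohort
    (propagating the single-arm sampling noise), so the percentile interval
    over replicate effect estimates reflects the total uncertainty — it is
    wider, on average, than the fixed-prediction plugin interval.
    Replicates whose refit fails are dropped and counted; more than 10%
    failures aborts.
    """
    if B < 100:
        raise ContractError(f"bootstrap needs B >= 100 replicates, got {B}")
    base_model = PrognosticRegression(training).fit().model
    vc = predict_virtual_controls(base_model, treated)
    continuous = treated.outcome_spec.scale == "continuous"
    if continuous:
        base = estimate_effect_continuous(treated, vc, level, model=base_model)
    else:
        base = estimate_effect_binary(treated, vc, level)

    rng = np.random.default_rng(seed)
    points = []
    failures = 0
    n_train = training.n
    n_arm = treated.n
    for b in range(B):
        idx = rng.integers(0, n_train, n_train)
        arm_idx = rng.integers(0, n_arm, n_arm)
        df = training.data.iloc[idx].copy()
        df["id"] = [f"b{b}_{i}" for i in range(n_train)]
        arm_df = treated.data.iloc[arm_idx].copy()
        arm_df["id"] = [f"a{b}_{i}" for i in range(n_arm)]
        try:
            boot_cohort = Cohort(df, training.schema, training.outcome_spec)
            boot_arm = Cohort(arm_df, treated.schema, treated.outcome_spec)
            m = PrognosticRegression(boot_cohort).fit().model
            v = predict_virtual_controls(m, boot_arm)
            if continuous:
                est = estimate_effect_continuous(
                    boot_arm, v, level, uncertainty="plugin"
                )
            else:
                est = estimate_effect_binary(boot_arm, v, level)
            points.append(est.point)
        except Exception:
            failures += 1
    if failures > 0.1 * B:
        raise ConvergenceError(
            f"bootstrap aborted: {failures}/{B} replicate refits failed"
        )
    pts = np.asarray(points)
    alpha = 1 - level
    ci = (float(np.quantile(pts, alpha / 2)), float(np.quantile(pts, 1 - alpha / 2)))
    extras = dict(base.extras)
    extras.update({"n_replicates": len(pts), "n_failed_replicates": failures})
    return EffectEstimate(
        measure=base.measure,
        point=base.point,
        ci=ci,
        level=level,
        statistic=base.statistic,
        pvalue=base.pvalue,
        method=base.method,
        n=base.n,
        uncertainty_mode="bootstrap-propagated",
        standardized=base.standardized,
        risk_ratio=base.risk_ratio,
        n_extrapolated=base.n_extrapolated,
        n_skipped=base.n_skipped,
        model_version=base.model_version,
        seed=seed,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# statsmodels-style surface


class SingleArmComparison:
    """Single-arm trial analysed against virtual controls.

    Parameters
    ----------
    treated : Cohort
        The single-arm cohort (all ``treated == 1``) with observed outcomes.
    prognostic : PrognosticModel or PrognosticResults
        The coefficient set fitted to untreated subjects.
    training : Cohort, optional
        Training data; required only for ``method='bootstrap'``.
    """

    def __init__(self, treated: Cohort, prognostic, training: Cohort | None = None):
        if isinstance(prognostic, PrognosticResults):
            self.model = prognostic.model
            self.training = training if training is not None else prognostic.training
        else:
            self.model = prognostic
            self.training = training
        self.treated = treated

    def fit(
        self,
        level: float = DEFAULT_LEVEL,
        method: str = "auto",
        B: int = 500,
        seed: int | None = None,
    ) -> "EffectResults":
        vc = predict_virtual_controls(self.model, self.treated)
        if method == "bootstrap":
            if self.training is None:
                raise ContractError("bootstrap propagation requires the training cohort")
            est = bootstrap_propagate(self.training, self.treated, B=B, seed=seed, level=level)
        elif self.treated.outcome_spec.scale == "continuous":
            est = estimate_effect_continuous(
                self.treated, vc, level, model=self.model,
                uncertainty="auto" if method == "auto" else method,
            )
        else:
            est = estimate_effect_binary(self.treated, vc, level, seed=seed)
        return EffectResults(estimate=est, virtual_controls=vc, model=self.model)


@dataclass(frozen=True)
class EffectResults:
    """Results of a virtual-control comparison: estimate + predictions."""

    estimate: EffectEstimate
    virtual_controls: VirtualControlSet
    model: PrognosticModel

    @property
    def point(self) -> float:
        return self.estimate.point

    @property
    def ci(self) -> tuple[float, float]:
        return self.estimate.ci

    @property
    def pvalue(self) -> float:
        return self.estimate.pvalue

    def summary(self) -> str:
        head = (
            f"Virtual-control comparison (model version {self.model.version}, "
            f"{self.virtual_controls.n} treated subjects)"
        )
        return head + "\n" + self.estimate.summary()
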