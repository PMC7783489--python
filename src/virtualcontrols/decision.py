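"""Per-patient counterfactual reporting — the clinical end-product.

Given prognostic coefficient sets fitted to untreated and to treated
subjects, :func:`patient_report` answers, for one patient's covariates:
"the predicted outcome without this intervention is X, and the predicted
outcome with this intervention is Y", with intervals and explicit
extrapolation warnings whenever the patient lies outside a model's
training support.

If no treated-subjects model exists yet, the report can degrade to
shifting the untreated prediction by a cohort-level
:class:`~virtualcontrols.estimator.EffectEstimate`; this is tagged as
arithmetic, never silently presented as an individualized model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.special import expit

from .cohort import PrognosticModel
from .estimator import EffectEstimate
from .exceptions import ContractError

DEFAULT_LEVEL = 0.95


def _design_vector(model: PrognosticModel, covariates: Mapping[str, object]) -> np.ndarray:
    """Patient covariates -> (1, dummies...) vector in the model's param order."""
    order = list(model.training_meta.param_order or ["(intercept)"] + model.schema.design_columns())
    vec = np.zeros(len(order))
    values: dict[str, float] = {}
    for v in model.schema.variables:
        if v.name not in covariates or covariates[v.name] is None:
            raise ContractError(f"patient is missing covariate {v.name!r}")
        val = covariates[v.name]
        if v.kind == "categorical":
            if str(val) not in v.levels:
                raise ContractError(f"level {val!r} of {v.name!r} not in {list(v.levels)}")
            for lev in v.levels[1:]:
                values[f"{v.name}[{lev}]"] = float(str(val) == lev)
        else:
            values[v.name] = float(val)
    for j, nm in enumerate(order):
        vec[j] = 1.0 if nm == "(intercept)" else values[nm]
    return vec


def _extrapolation_warnings(model: PrognosticModel, covariates: Mapping) -> tuple[str, ...]:
    warns = []
    for v in model.schema.variables:
        if v.kind == "continuous" and v.support is not None:
            val = float(covariates[v.name])
            lo, hi = v.support
            if val < lo or val > hi:
                warns.append(
                    f"{v.name}={val:g} outside training support [{lo:g}, {hi:g}]"
                )
    return tuple(warns)


def _predict_with_interval(model: PrognosticModel, covariates: Mapping, level: float):
    """(point, (lo, hi) or None, method tag) for one patient."""
    a = _design_vector(model, covariates)
    names, params = model.param_vector()
    lp = float(a @ params)
    cov = model.training_meta.cov_matrix()
    if cov is None:
        point = expit(lp) if model.family == "logistic" else lp
        return point, None, "point-only (no training covariance stored)"
    se = float(np.sqrt(max(a @ cov @ a, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = lp - z * se, lp + z * se
    if model.family == "logistic":
        return float(expit(lp)), (float(expit(lo)), float(expit(hi))), "linear-predictor-variance"
    return lp, (lo, hi), "linear-predictor-variance"


@dataclass(frozen=True)
class PatientReport:
    """With/without-intervention predictions for one patient."""

    covariates: dict
    scale: str
    without_intervention: float
    without_interval: tuple[float, float] | None
    with_intervention: float
    with_interval: tuple[float, float] | None
    level: float
    method: str
    extrapolation_warnings_untreated: tuple[str, ...]
    extrapolation_warnings_treated: tuple[str, ...]
    model_version_untreated: int
    model_version_treated: int | None

    def summary(self) -> str:
        def fmt(x, iv):
            unit = "probability " if self.scale == "binary" else ""
            s = f"{unit}{x:.3f}"
            if iv is not None:
                s += f" ({int(self.level*100)}% interval {iv[0]:.3f} to {iv[1]:.3f})"
            return s

        lines = [
            "Given your data,",
            f"  the predicted outcome without this intervention is "
            f"{fmt(self.without_intervention, self.without_interval)},",
            f"  and the predicted outcome with this intervention is "
            f"{fmt(self.with_intervention, self.with_interval)}.",
            f"  [method: {self.method}; untreated model v{self.model_version_untreated}"
            + (
                f", treated model v{self.model_version_treated}]"
                if self.model_version_treated is not None
                else "]"
            ),
        ]
        for w in self.extrapolation_warnings_untreated:
            lines.append(f"  warning (untreated model): {w}")
        for w in self.extrapolation_warnings_treated:
            lines.append(f"  warning (treated model): {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "covariates": dict(self.covariates),
            "scale": self.scale,
            "without_intervention": self.without_intervention,
            "without_interval": list(self.without_interval) if self.without_interval else None,
            "with_intervention": self.with_intervention,
            "with_interval": list(self.with_interval) if self.with_interval else None,
            "level": self.level,
            "method": self.method,
            "extrapolation_warnings_untreated": list(self.extrapolation_warnings_untreated),
            "extrapolation_warnings_treated": list(self.extrapolation_warnings_treated),
            "model_version_untreated": self.model_version_untreated,
            "model_version_treated": self.model_version_treated,
        }


def patient_report(
    model_untreated: PrognosticModel,
    model_treated: PrognosticModel | None,
    covariates: Mapping[str, object],
    effect: EffectEstimate | None = None,
    level: float = DEFAULT_LEVEL,
) -> PatientReport:
    """Predict a patient's outcome with and without the intervention.

    The with-intervention prediction comes from a treated-subjects model
    when one exists; only if ``model_treated`` is None does the report fall
    back to shifting the untreated prediction by a cohort-level effect
    estimate (continuous scale only, tagged ``effect-shift-arithmetic``).
    A report is a pure function of its inputs.
    """
    without, w_iv, method = _predict_with_interval(model_untreated, covariates, level)
    warns_u = _extrapolation_warnings(model_untreated, covariates)

    if model_treated is not None:
        if model_treated.outcome_spec.scale != model_untreated.outcome_spec.scale:
            raise ContractError(
                "treated and untreated models must share the outcome scale: "
                f"{model_treated.outcome_spec.scale} vs {model_untreated.outcome_spec.scale}"
            )
        with_, t_iv, method2 = _predict_with_interval(model_treated, covariates, level)
        warns_t = _extrapolation_warnings(model_treated, covariates)
        return PatientReport(
            covariates=dict(covariates),
            scale=model_untreated.outcome_spec.scale,
            without_intervention=without,
            without_interval=w_iv,
            with_intervention=with_,
            with_interval=t_iv,
            level=level,
            method=method if method == method2 else f"{method} / {method2}",
            extrapolation_warnings_untreated=warns_u,
            extrapolation_warnings_treated=warns_t,
            model_version_untreated=model_untreated.version,
            model_version_treated=model_treated.version,
        )

    if effect is None:
        raise ContractError(
            "need either a treated-subjects model or a cohort-level effect estimate"
        )
    if model_untreated.outcome_spec.scale != "continuous" or effect.measure != "mean-added-value":
        raise ContractError(
            "effect-shift fallback is defined for continuous outcomes with a "
            "mean-added-value estimate only"
        )
    half = (effect.ci[1] - effect.ci[0]) / 2
    with_ = without + effect.point
    t_iv = (with_ - half, with_ + half)
    return PatientReport(
        covariates=dict(covariates),
        scale="continuous",
        without_intervention=without,
        without_interval=w_iv,
        with_intervention=with_,
        with_interval=t_iv,
        level=effect.level,
        method=f"{method}; with-intervention by effect-shift-arithmetic "
        "(no treated-subjects model available)",
        extrapolation_warnings_untreated=warns_u,
        extrapolation_warnings_treated=(),
        model_version_untreated=model_untreated.version,
        model_version_treated=None,
    )
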