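"""Fitting, validating and pooling prognostic models.

The prognostic model is the engine of the virtual-controls design: an
ordinary linear regression (continuous outcome) or logistic regression
(binary outcome) fitted to *untreated* subjects, whose predictions for
later treated subjects serve as per-patient counterfactuals.

The statsmodels-style surface is :class:`PrognosticRegression` (a model
built from a training cohort) whose ``fit()`` returns
:class:`PrognosticResults` carrying coefficient estimates, their covariance,
the precision index (R-square / Brier), a ``summary()`` table, and the
portable :class:`~virtualcontrols.cohort.PrognosticModel` artifact.
Functional wrappers (``fit_prognostic_model``, ``model_precision``,
``validate_external``, ``pool_and_refit``) expose the same operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import (
    Cohort,
    CovariateSchema,
    OutcomeSpec,
    PrognosticModel,
    TrainingMeta,
    Variable,
    design_matrix,
    write_model,
)
from .exceptions import (
    ContractError,
    ConvergenceError,
    SchemaError,
    SingularityError,
)

MAX_LOGISTIC_ITER = 100  # iteration cap for the logistic MLE
LOGISTIC_TOL = 1e-8  # tolerance on the log-likelihood change

_UNDEFINED = None  # sentinel for undefined calibration quantities


@dataclass(frozen=True)
class ValidationReport:
    """Accuracy of a prognostic model on a cohort.

    For the linear family: R-square, mean error (observed - predicted) and
    the calibration regression of observed on predicted (slope 1 /
    intercept 0 is perfect calibration).  For the logistic family the
    calibration regression is on the linear predictor, and the Brier score
    and mean observed vs. predicted event rates are reported.  A
    zero-variance prediction vector makes the calibration slope undefined;
    it is reported as ``None``, never raised.
    """

    n: int
    family: str
    r_squared: float | None = None
    mean_error: float | None = None
    calibration_slope: float | None = None
    calibration_intercept: float | None = None
    brier: float | None = None
    mean_observed: float | None = None
    mean_predicted: float | None = None
    truncation_warnings: tuple[str, ...] = ()
    n_excluded_missing: int = 0

    def summary(self) -> str:
        lines = [f"Validation report ({self.family} family, n={self.n})"]
        if self.family == "linear":
            lines.append(f"  R-square:              {self.r_squared:.4f}")
            lines.append(f"  mean error (obs-pred): {self.mean_error:.4f}")
        else:
            lines.append(f"  Brier score:           {self.brier:.4f}")
            lines.append(f"  mean observed rate:    {self.mean_observed:.4f}")
            lines.append(f"  mean predicted rate:   {self.mean_predicted:.4f}")
        slope = "undefined" if self.calibration_slope is None else f"{self.calibration_slope:.4f}"
        icpt = (
            "undefined"
            if self.calibration_intercept is None
            else f"{self.calibration_intercept:.4f}"
        )
        lines.append(f"  calibration slope:     {slope}")
        lines.append(f"  calibration intercept: {icpt}")
        if self.truncation_warnings:
            lines.append("  truncation warnings:")
            for w in self.truncation_warnings:
                lines.append(f"    - {w}")
        if self.n_excluded_missing:
            lines.append(f"  rows excluded for missing covariates: {self.n_excluded_missing}")
        return "\n".join(lines)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise SingularityError naming collinear design columns."""
    if X.shape[0] == 0:
        return
    Xa = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(Xa)
    if rank >= Xa.shape[1]:
        return
    _, R, piv = qr(Xa, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xa.shape) * np.finfo(float).eps
    bad = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
    all_names = ["(intercept)"] + list(names)
    cols = [all_names[j] for j in sorted(bad)]
    raise SingularityError(
        f"design matrix is rank deficient (rank {rank} < {Xa.shape[1]}); "
        f"collinear column(s): {cols}",
        columns=cols,
    )


class PrognosticRegression:
    """Prognostic regression model built from an untreated training cohort.

    Parameters
    ----------
    training : Cohort
        Untreated subjects only (``treated == 0`` for every row); the model
        family follows the outcome scale (continuous -> linear, binary ->
        logistic).  Rows with missing covariates are excluded from the fit
        and reported on the results object, never imputed.
    provenance : str
        Free-text note stored in the coefficient set's training metadata.
    """

    def __init__(self, training: Cohort, provenance: str = ""):
        if not training.all_untreated():
            n_treated = int(training.treated_mask.sum())
            raise ContractError(
                f"training cohort must contain only untreated subjects; "
                f"{n_treated} treated row(s) present"
            )
        self.training = training
        self.provenance = provenance
        self.family = "linear" if training.outcome_spec.scale == "continuous" else "logistic"

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        scale: str = "continuous",
        schema: CovariateSchema | None = None,
        provenance: str = "",
    ) -> "PrognosticRegression":
        """Build from a raw table; covariates default to every numeric
        column except id/treated/outcome, treated as continuous."""
        if schema is None:
            skip = {"id", "treated", outcome}
            names = [c for c in df.columns if c not in skip]
            schema = CovariateSchema(tuple(Variable(n) for n in names))
        if "id" not in df.columns:
            df = df.copy()
            df["id"] = [f"s{i}" for i in range(len(df))]
        if "treated" not in df.columns:
            df = df.assign(treated=0)
        cohort = Cohort(df, schema, OutcomeSpec(outcome, scale))
        return cls(cohort, provenance=provenance)

    def fit(self, version: int = 1) -> "PrognosticResults":
        cohort = self.training
        mask = cohort.complete_covariate_mask()
        excluded = cohort.ids[~mask].tolist()
        if excluded:
            warnings.warn(
                f"{len(excluded)} row(s) excluded from fit for missing covariates",
                stacklevel=2,
            )
        work = cohort.subset(mask)
        X, names, _ = design_matrix(work)
        y = pd.to_numeric(work.outcome, errors="coerce").to_numpy(dtype=float)
        n, k = X.shape
        if n <= k + 1:
            raise ContractError(
                f"training n={n} must exceed parameter count {k + 1}"
            )
        _check_rank(X, names)
        Xa = sm.add_constant(X, has_constant="add")

        if self.family == "linear":
            res = sm.OLS(y, Xa).fit()
            precision: float | dict = float(res.rsquared)
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", category=PerfectSeparationWarning)
                    warnings.simplefilter("ignore", category=ConvergenceWarning)
                    res = sm.Logit(y, Xa).fit(
                        disp=0, maxiter=MAX_LOGISTIC_ITER, tol=LOGISTIC_TOL
                    )
            except (PerfectSeparationError, PerfectSeparationWarning) as exc:
                raise ConvergenceError(
                    f"logistic fit did not converge (separation detected): {exc}",
                    iterations=MAX_LOGISTIC_ITER,
                ) from exc
            if not res.mle_retvals.get("converged", False):
                raise ConvergenceError(
                    "logistic MLE did not converge within "
                    f"{MAX_LOGISTIC_ITER} iterations",
                    iterations=res.mle_retvals.get("iterations", MAX_LOGISTIC_ITER),
                )
            p_hat = res.predict(Xa)
            precision = {
                "brier": float(np.mean((p_hat - y) ** 2)),
                "mean_event_rate": float(np.mean(y)),
            }

        supports = {
            v.name: (float(work.data[v.name].min()), float(work.data[v.name].max()))
            for v in cohort.schema.variables
            if v.kind == "continuous"
        }
        schema = cohort.schema.with_support(supports)
        param_order = ["(intercept)"] + names
        meta = TrainingMeta(
            n=n,
            precision=precision,
            version=version,
            provenance=self.provenance,
            param_order=tuple(param_order),
            cov_params=tuple(tuple(float(x) for x in row) for row in res.cov_params()),
        )
        artifact = PrognosticModel(
            family=self.family,
            intercept=float(res.params[0]),
            coefficients={nm: float(b) for nm, b in zip(names, res.params[1:])},
            schema=schema,
            training_meta=meta,
            outcome_spec=cohort.outcome_spec,
        )
        return PrognosticResults(
            model=artifact,
            training=cohort,
            sm_results=res,
            excluded_ids=tuple(excluded),
        )


@dataclass(frozen=True)
class PrognosticResults:
    """Fitted prognostic model: coefficient set plus fit diagnostics."""

    model: PrognosticModel
    training: Cohort
    sm_results: object
    excluded_ids: tuple[str, ...] = ()

    @property
    def params(self) -> pd.Series:
        names, vals = self.model.param_vector()
        return pd.Series(vals, index=names)

    @property
    def bse(self) -> pd.Series:
        names, _ = self.model.param_vector()
        return pd.Series(np.sqrt(np.diag(self.sm_results.cov_params())), index=names)

    def cov_params(self) -> np.ndarray:
        return np.asarray(self.sm_results.cov_params())

    @property
    def rsquared(self) -> float | None:
        if self.model.family == "linear":
            return float(self.model.training_meta.precision)
        return None

    @property
    def version(self) -> int:
        return self.model.version

    def save(self, path) -> None:
        write_model(self.model, path)

    def predict(self, cohort: Cohort):
        """Virtual controls for a treated cohort (see estimator module)."""
        from .estimator import predict_virtual_controls

        return predict_virtual_controls(self.model, cohort)

    def validate(self, cohort: Cohort, external: bool = True) -> ValidationReport:
        if external:
            return validate_external(self.model, cohort)
        return model_precision(self.model, cohort)

    def pool_and_refit(self, new_cohorts: Sequence[Cohort]) -> "PrognosticResults":
        return pool_and_refit(self, new_cohorts)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Prognostic model ({m.family} family), version {m.version}",
            f"  training n: {m.training_meta.n}"
            + (f", excluded for missingness: {len(self.excluded_ids)}" if self.excluded_ids else ""),
        ]
        if m.family == "linear":
            lines.append(f"  R-square: {m.training_meta.precision:.4f}")
        else:
            prec = m.training_meta.precision
            lines.append(
                f"  Brier: {prec['brier']:.4f}, mean event rate: {prec['mean_event_rate']:.4f}"
            )
        lines.append(f"  {'term':<20s} {'coef':>10s} {'se':>10s}")
        for name, b, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"  {name:<20s} {b:>10.4f} {se:>10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# prediction helpers shared with the estimator module


def linear_predictor(model: PrognosticModel, cohort: Cohort) -> tuple[np.ndarray, pd.Series]:
    """Intercept + sum(coefficient * value) per subject; (values, complete mask)."""
    X, names, mask = design_matrix(cohort, model.schema)
    beta = np.array([model.coefficients.get(nm, 0.0) for nm in names])
    lp = model.intercept + X @ beta
    return lp, mask


def predicted_outcome(model: PrognosticModel, cohort: Cohort) -> tuple[np.ndarray, pd.Series]:
    lp, mask = linear_predictor(model, cohort)
    if model.family == "logistic":
        return 1.0 / (1.0 + np.exp(-lp)), mask
    return lp, mask


def truncation_flags(model: PrognosticModel, cohort: Cohort) -> pd.DataFrame:
    """Per-subject, per-covariate indicator of values outside model support."""
    flags = {}
    for v in model.schema.variables:
        col = pd.to_numeric(cohort.data[v.name], errors="coerce") if v.kind != "categorical" else None
        if v.kind == "continuous" and v.support is not None:
            lo, hi = v.support
            flags[v.name] = ((col < lo) | (col > hi)).fillna(False)
        elif v.kind == "categorical":
            flags[v.name] = ~cohort.data[v.name].astype(str).isin(v.levels)
        else:
            flags[v.name] = pd.Series(False, index=cohort.data.index)
    return pd.DataFrame(flags, index=cohort.data.index)


# ---------------------------------------------------------------------------
# functional operation surface


def fit_prognostic_model(
    training: Cohort, provenance: str = "", version: int = 1
) -> PrognosticModel:
    """Fit on untreated subjects; returns the portable coefficient set."""
    return PrognosticRegression(training, provenance=provenance).fit(version=version).model


def _calibration(y: np.ndarray, pred: np.ndarray, family: str):
    """Observed-on-predicted calibration; logistic calibrates on the logit."""
    if np.var(pred) < 1e-12:
        return _UNDEFINED, _UNDEFINED
    if family == "linear":
        res = sm.OLS(y, sm.add_constant(pred)).fit()
        return float(res.params[1]), float(res.params[0])
    lp = np.log(pred / (1 - pred))
    try:
        res = sm.Logit(y, sm.add_constant(lp)).fit(disp=0, maxiter=MAX_LOGISTIC_ITER)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return _UNDEFINED, _UNDEFINED
    return float(res.params[1]), float(res.params[0])


def model_precision(model: PrognosticModel, cohort: Cohort) -> ValidationReport:
    """In-sample accuracy; on the training data this reproduces the stored
    precision index."""
    if set(cohort.schema.names) != set(model.schema.names):
        raise ContractError(
            f"cohort covariates {cohort.schema.names} do not match model "
            f"schema {model.schema.names}"
        )
    mask = cohort.complete_covariate_mask()
    work = cohort.subset(mask)
    pred, _ = predicted_outcome(model, work)
    y = pd.to_numeric(work.outcome, errors="coerce").to_numpy(dtype=float)
    slope, icpt = _calibration(y, pred, model.family)
    if model.family == "linear":
        sse = float(np.sum((y - pred) ** 2))
        sst = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else _UNDEFINED
        return ValidationReport(
            n=len(y),
            family="linear",
            r_squared=r2,
            mean_error=float(np.mean(y - pred)),
            calibration_slope=slope,
            calibration_intercept=icpt,
            n_excluded_missing=int((~mask).sum()),
        )
    return ValidationReport(
        n=len(y),
        family="logistic",
        brier=float(np.mean((pred - y) ** 2)),
        mean_observed=float(np.mean(y)),
        mean_predicted=float(np.mean(pred)),
        calibration_slope=slope,
        calibration_intercept=icpt,
        n_excluded_missing=int((~mask).sum()),
    )


def validate_external(model: PrognosticModel, independent: Cohort) -> ValidationReport:
    """Out-of-sample check on an independently collected untreated cohort.

    Besides the accuracy indices, lists every covariate whose observed range
    extends beyond the model's training support — the cue that the training
    sample should be enlarged before generalising the equations.
    """
    if not independent.all_untreated():
        raise ContractError("external validation cohort must be untreated")
    report = model_precision(model, independent)
    flags = truncation_flags(model, independent)
    warn = tuple(
        f"{name}: {int(flags[name].sum())} subject(s) outside training support"
        for name in flags.columns
        if flags[name].any()
    )
    return replace(report, truncation_warnings=warn)


def _unify_schemas(schemas: Iterable[CovariateSchema]) -> CovariateSchema:
    variables: dict[str, Variable] = {}
    for schema in schemas:
        for v in schema.variables:
            if v.name not in variables:
                variables[v.name] = replace(v, support=None)
            else:
                old = variables[v.name]
                if old.kind != v.kind:
                    raise SchemaError(
                        f"schema conflict: variable {v.name!r} is {old.kind} in one "
                        f"cohort and {v.kind} in another"
                    )
                if v.kind == "categorical":
                    merged = tuple(old.levels) + tuple(
                        l for l in v.levels if l not in old.levels
                    )
                    variables[v.name] = replace(old, levels=merged)
    return CovariateSchema(tuple(variables.values()))


def pool_and_refit(
    fitted: PrognosticResults, new_cohorts: Sequence[Cohort]
) -> PrognosticResults:
    """Concatenate the training data with new untreated cohorts and refit.

    New variables extend the schema; rows from cohorts that never measured
    such a variable are treated as missing there (and therefore excluded
    from the extended fit).  The refit model's version is incremented and
    its support intervals widen to the pooled ranges.
    """
    for c in new_cohorts:
        if not c.all_untreated():
            raise ContractError("pooled cohorts must be untreated")
        if c.outcome_spec != fitted.training.outcome_spec:
            raise SchemaError(
                f"outcome spec mismatch: {c.outcome_spec} vs {fitted.training.outcome_spec}"
            )
    schema = _unify_schemas(
        [fitted.training.schema] + [c.schema for c in new_cohorts]
    )
    frames = [fitted.training.data] + [c.data for c in new_cohorts]
    pooled = pd.concat(frames, ignore_index=True)
    # re-key ids to keep uniqueness across sources
    pooled["id"] = [f"p{i}:{sid}" for i, sid in enumerate(pooled["id"])]
    for v in schema.variables:
        if v.name not in pooled.columns:
            pooled[v.name] = np.nan
    cohort = Cohort(pooled, schema, fitted.training.outcome_spec)
    reg = PrognosticRegression(cohort, provenance=fitted.model.training_meta.provenance)
    return reg.fit(version=fitted.model.version + 1)
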