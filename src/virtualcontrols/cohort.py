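"""Cohort and coefficient-set data model with delimited-text I/O.

A :class:`Cohort` is the universal tabular input: one row per subject with a
unique text id, covariate columns described by a :class:`CovariateSchema`, a
0/1 ``treated`` indicator and an outcome column (continuous value or 0/1
event indicator).  A :class:`PrognosticModel` is the portable "set of
coefficients" research product: model family, intercept, per-variable
coefficients, the schema (including the covariate support observed at
training time) and training metadata, serialised losslessly to JSON.

Files are comma-delimited UTF-8 with a header row and "." decimal.  Rows
that violate type constraints are rejected with row-level diagnostics —
never silently dropped.  Missing covariate values are explicit (empty field
or NaN) and flagged downstream, not imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CohortValidationError,
    ContractError,
    FormatError,
    SchemaError,
)

VARIABLE_KINDS = ("continuous", "binary", "categorical")
MODEL_FAMILIES = ("linear", "logistic")


@dataclass(frozen=True)
class Variable:
    """One covariate: name, measurement kind and (for continuous) support.

    ``support`` is the observed (min, max) interval recorded at training
    time; predictions outside it are flagged as extrapolation.  Categorical
    variables carry their levels; the first listed level is the dummy-coding
    reference.
    """

    name: str
    kind: str = "continuous"
    support: tuple[float, float] | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in VARIABLE_KINDS:
            raise SchemaError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise SchemaError(
                    f"categorical variable {self.name!r} must list >= 2 levels"
                )
        if self.support is not None:
            lo, hi = self.support
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
                raise SchemaError(
                    f"support interval for {self.name!r} must be finite with min <= max"
                )

    def design_columns(self) -> list[str]:
        """Names of the design-matrix columns this variable expands to."""
        if self.kind == "categorical":
            return [f"{self.name}[{lev}]" for lev in self.levels[1:]]
        return [self.name]


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate description shared by cohorts and models."""

    variables: tuple[Variable, ...]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("covariate names must be unique")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def design_columns(self) -> list[str]:
        cols: list[str] = []
        for v in self.variables:
            cols.extend(v.design_columns())
        return cols

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def with_support(self, supports: Mapping[str, tuple[float, float]]) -> "CovariateSchema":
        """Return a copy with continuous support intervals replaced."""
        new = []
        for v in self.variables:
            if v.name in supports and v.kind == "continuous":
                new.append(replace(v, support=tuple(map(float, supports[v.name]))))
            else:
                new.append(v)
        return CovariateSchema(tuple(new))

    @classmethod
    def from_dict(cls, spec: Sequence[Mapping]) -> "CovariateSchema":
        vs = []
        for item in spec:
            vs.append(
                Variable(
                    name=item["name"],
                    kind=item.get("kind", "continuous"),
                    support=tuple(item["support"]) if item.get("support") else None,
                    levels=tuple(item["levels"]) if item.get("levels") else None,
                )
            )
        return cls(tuple(vs))

    def to_dict(self) -> list[dict]:
        out = []
        for v in self.variables:
            d: dict = {"name": v.name, "kind": v.kind}
            if v.support is not None:
                d["support"] = [float(v.support[0]), float(v.support[1])]
            if v.levels is not None:
                d["levels"] = list(v.levels)
            out.append(d)
        return out


@dataclass(frozen=True)
class OutcomeSpec:
    """Outcome column name and scale; the scale is declared, never inferred."""

    name: str
    scale: str  # "continuous" | "binary"

    def __post_init__(self):
        if self.scale not in ("continuous", "binary"):
            raise SchemaError(f"outcome scale must be continuous or binary, got {self.scale!r}")


RESERVED_COLUMNS = ("id", "treated")


@dataclass
class Cohort:
    """Validated subject table.

    ``data`` columns: ``id`` (unique text), one column per schema variable,
    ``treated`` (0/1) and the outcome column named by ``outcome_spec``.
    Extra columns (e.g. RCT preference bookkeeping) are carried through
    untouched.
    """

    data: pd.DataFrame
    schema: CovariateSchema
    outcome_spec: OutcomeSpec

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        required = ["id", "treated", self.outcome_spec.name] + self.schema.names
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort is missing required column(s): {missing}")

        bad_rows: list[tuple[int, str]] = []
        ids = df["id"].astype(str)
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise CohortValidationError(f"duplicate subject ids: {dup}")

        treated = df["treated"]
        for i, t in treated.items():
            if t not in (0, 1, True, False):
                bad_rows.append((i, f"treated must be 0/1, got {t!r}"))

        y = df[self.outcome_spec.name]
        if self.outcome_spec.scale == "binary":
            for i, v in y.items():
                if pd.isna(v):
                    bad_rows.append((i, "missing outcome"))
                elif v not in (0, 1, 0.0, 1.0):
                    bad_rows.append(
                        (i, f"binary outcome must be 0/1, got {v!r} in column "
                            f"{self.outcome_spec.name!r}")
                    )
        else:
            numeric = pd.to_numeric(y, errors="coerce")
            for i in y.index[numeric.isna() & y.notna()]:
                bad_rows.append((i, f"non-numeric outcome {y[i]!r}"))

        for v in self.schema.variables:
            col = df[v.name]
            if v.kind == "binary":
                for i, x in col.items():
                    if pd.notna(x) and x not in (0, 1, 0.0, 1.0):
                        bad_rows.append((i, f"binary covariate {v.name!r} must be 0/1, got {x!r}"))
            elif v.kind == "categorical":
                for i, x in col.items():
                    if pd.notna(x) and str(x) not in v.levels:
                        bad_rows.append(
                            (i, f"level {x!r} of {v.name!r} not in {list(v.levels)}")
                        )
            else:
                numeric = pd.to_numeric(col, errors="coerce")
                for i in col.index[numeric.isna() & col.notna()]:
                    bad_rows.append((i, f"non-numeric value {col[i]!r} in {v.name!r}"))

        if bad_rows:
            lines = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:20])
            raise CohortValidationError(
                f"{len(bad_rows)} invalid row(s): {lines}", rows=bad_rows
            )

        self.data["id"] = ids
        self.data["treated"] = df["treated"].astype(int)

    # -- convenience -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data["id"]

    @property
    def outcome(self) -> pd.Series:
        return self.data[self.outcome_spec.name]

    @property
    def treated_mask(self) -> pd.Series:
        return self.data["treated"] == 1

    def all_untreated(self) -> bool:
        return bool((self.data["treated"] == 0).all())

    def all_treated(self) -> bool:
        return bool((self.data["treated"] == 1).all())

    def complete_covariate_mask(self) -> pd.Series:
        """True for rows with no missing covariate values."""
        return self.data[self.schema.names].notna().all(axis=1)

    def subset(self, mask) -> "Cohort":
        return Cohort(self.data.loc[mask].copy(), self.schema, self.outcome_spec)

    def equals(self, other: "Cohort") -> bool:
        if self.schema != other.schema or self.outcome_spec != other.outcome_spec:
            return False
        a = self.data[["id", "treated", self.outcome_spec.name] + self.schema.names]
        b = other.data[["id", "treated", other.outcome_spec.name] + other.schema.names]
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True


def design_matrix(
    cohort: Cohort, schema: CovariateSchema | None = None
) -> tuple[np.ndarray, list[str], pd.Series]:
    """Expand covariates to a numeric design matrix (no intercept column).

    Categorical variables become reference-level dummy columns.  Returns
    (matrix, column names, complete-row mask); rows with missing covariates
    appear in the matrix as NaN and in the mask as False.
    """
    schema = schema or cohort.schema
    df = cohort.data
    cols: list[np.ndarray] = []
    names: list[str] = []
    for v in schema.variables:
        if v.name not in df.columns:
            raise ContractError(f"cohort lacks covariate {v.name!r} required by schema")
        col = df[v.name]
        if v.kind == "categorical":
            s = col.astype("object")
            for lev in v.levels[1:]:
                x = np.where(s.isna(), np.nan, (s.astype(str) == lev).astype(float))
                cols.append(x)
                names.append(f"{v.name}[{lev}]")
        else:
            cols.append(pd.to_numeric(col, errors="coerce").to_numpy(dtype=float))
            names.append(v.name)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    mask = pd.Series(~np.isnan(X).any(axis=1) if X.size else True, index=df.index)
    return X, names, mask


@dataclass(frozen=True)
class TrainingMeta:
    """Provenance of a fitted coefficient set.

    ``precision`` is the model's own accuracy index: R-square for the linear
    family; for logistic, a dict with Brier score and mean event rate.
    ``cov_params`` (optional) is the coefficient covariance matrix in
    ``param_order`` — kept so that downstream estimates can propagate
    training uncertainty analytically.
    """

    n: int
    precision: float | Mapping[str, float]
    version: int = 1
    provenance: str = ""
    param_order: tuple[str, ...] | None = None
    cov_params: tuple[tuple[float, ...], ...] | None = None

    def cov_matrix(self) -> np.ndarray | None:
        if self.cov_params is None:
            return None
        return np.asarray(self.cov_params, dtype=float)


@dataclass(frozen=True)
class PrognosticModel:
    """A versioned prognostic coefficient set.

    ``coefficients`` maps design-column names (categorical levels expanded)
    to real coefficients.  Together with ``intercept`` and ``family`` this
    is everything needed to predict a counterfactual outcome for a new
    subject; the schema's support intervals delimit where prediction is
    interpolation rather than extrapolation.
    """

    family: str
    intercept: float
    coefficients: Mapping[str, float]
    schema: CovariateSchema
    training_meta: TrainingMeta
    outcome_spec: OutcomeSpec

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise FormatError(f"unknown model family {self.family!r}")
        allowed = set(self.schema.design_columns())
        extra = set(self.coefficients) - allowed
        if extra:
            raise SchemaError(f"coefficients {sorted(extra)} not in schema design columns")
        if self.training_meta.version < 1:
            raise SchemaError("model version must be >= 1")
        n_params = len(self.coefficients) + 1
        if self.training_meta.n < n_params + 1:
            raise SchemaError(
                f"training n={self.training_meta.n} must exceed parameter count {n_params}"
            )

    @property
    def version(self) -> int:
        return self.training_meta.version

    def param_vector(self) -> tuple[list[str], np.ndarray]:
        """(names, values) with the intercept first, in schema order."""
        names = ["(intercept)"] + self.schema.design_columns()
        vals = [self.intercept] + [
            float(self.coefficients.get(c, 0.0)) for c in self.schema.design_columns()
        ]
        return names, np.asarray(vals)


# ---------------------------------------------------------------------------
# delimited-text cohort I/O


def read_cohort(path, outcome_spec: OutcomeSpec, schema: CovariateSchema) -> Cohort:
    """Read a comma-delimited cohort file and validate it against the schema."""
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse cohort file {path}: {exc}") from exc
    required = ["id", "treated", outcome_spec.name] + schema.names
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} lacks column(s): {missing}")
    for v in schema.variables:
        if v.kind == "categorical":
            df[v.name] = df[v.name].astype("object")
    return Cohort(df, schema, outcome_spec)


def write_cohort(cohort: Cohort, path) -> None:
    cols = ["id", "treated", cohort.outcome_spec.name] + cohort.schema.names
    extras = [c for c in cohort.data.columns if c not in cols]
    cohort.data[cols + extras].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# coefficient-set (PrognosticModel) I/O — JSON with explicit schema block

_MODEL_REQUIRED = ("family", "intercept", "coefficients", "schema", "outcome", "training")


def write_model(model: PrognosticModel, path) -> None:
    doc = {
        "format": "virtualcontrols-model/1",
        "family": model.family,
        "intercept": model.intercept,
        "coefficients": {k: float(v) for k, v in model.coefficients.items()},
        "schema": model.schema.to_dict(),
        "outcome": {"name": model.outcome_spec.name, "scale": model.outcome_spec.scale},
        "training": {
            "n": model.training_meta.n,
            "precision": model.training_meta.precision,
            "version": model.training_meta.version,
            "provenance": model.training_meta.provenance,
            "param_order": list(model.training_meta.param_order)
            if model.training_meta.param_order
            else None,
            "cov_params": [list(row) for row in model.training_meta.cov_params]
            if model.training_meta.cov_params
            else None,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path) -> PrognosticModel:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse model file {path}: {exc}") from exc
    missing = [k for k in _MODEL_REQUIRED if k not in doc]
    if missing:
        raise FormatError(f"model file {path} missing field(s): {missing}")
    tr = doc["training"]
    meta = TrainingMeta(
        n=int(tr["n"]),
        precision=tr["precision"],
        version=int(tr["version"]),
        provenance=tr.get("provenance", ""),
        param_order=tuple(tr["param_order"]) if tr.get("param_order") else None,
        cov_params=tuple(tuple(row) for row in tr["cov_params"])
        if tr.get("cov_params")
        else None,
    )
    return PrognosticModel(
        family=doc["family"],
        intercept=float(doc["intercept"]),
        coefficients={k: float(v) for k, v in doc["coefficients"].items()},
        schema=CovariateSchema.from_dict(doc["schema"]),
        training_meta=meta,
        outcome_spec=OutcomeSpec(doc["outcome"]["name"], doc["outcome"]["scale"]),
    )
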