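"""Monte-Carlo operating characteristics: when do virtual controls give the
right answer, and when does randomization?

``run_cell`` evaluates one scenario cell under either design:

* virtual-control — per replicate, generate an untreated training cohort,
  fit the prognostic model, generate a treated single-arm cohort under the
  scenario's selection mechanism, predict virtual controls, estimate;
* randomized — generate a two-arm cohort (with preference/demoralization
  mechanics) and use the standard two-sample comparison.

Aggregated over replicates: bias, RMSE, empirical CI coverage of the true
effect, and the rejection rate of the two-sided alpha-level test against
zero (type-I error when tau = 0, power otherwise), each with its Monte
Carlo standard error.  ``r2_sweep`` back-solves the residual s.d. for a
grid of target prognostic R-square values and reports the smallest
R-square meeting a power threshold — the "how accurate does prediction
have to be" question.  ``power_two_proportion`` is the exact (enumeration)
or normal-approximation power of a two-sample proportion comparison, for
rare-event sample-size reasoning.

Replicate r of a cell seeded with ``seed`` draws its three random streams
from ``default_rng([seed, r, k])`` with k = 0 (training), 1 (single-arm),
2 (randomized) — a documented counter scheme making every cell
independently reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import (
    estimate_effect_binary,
    estimate_effect_continuous,
    predict_virtual_controls,
)
from .exceptions import ConfigurationError, ContractError
from .prognostic import PrognosticRegression
from .simulate import (
    GroundTruth,
    SimulationScenario,
    generate_rct_cohort,
    generate_single_arm_cohort,
    generate_training_cohort,
)

DEFAULT_ALPHA = 0.05  # two-sided decision rule against zero effect
MAX_FAILURE_FRACTION = 0.05

DESIGNS = ("virtual-control", "randomized")


@dataclass(frozen=True)
class OpCharCell:
    """Aggregated operating characteristics for one (scenario, design) cell."""

    design: str
    n_reps: int
    n_failed: int
    true_tau: float
    true_r2: float
    expected_bias: float
    bias: float
    bias_mc_se: float
    rmse: float
    coverage: float
    coverage_mc_se: float
    rejection_rate: float
    rejection_mc_se: float
    alpha: float
    level: float
    runtime_seconds: float
    valid: bool

    def summary(self) -> str:
        kind = "type-I error" if self.true_tau == 0 else "power"
        lines = [
            f"Operating characteristics ({self.design}, {self.n_reps} reps"
            + (f", {self.n_failed} failed" if self.n_failed else "")
            + ")",
            f"  true tau: {self.true_tau:.4f}   true R-square: {self.true_r2:.4f}",
            f"  bias:     {self.bias:+.4f} (MC se {self.bias_mc_se:.4f}; "
            f"expected under scenario {self.expected_bias:+.4f})",
            f"  RMSE:     {self.rmse:.4f}",
            f"  {int(self.level*100)}% CI coverage: {self.coverage:.3f} "
            f"(MC se {self.coverage_mc_se:.3f})",
            f"  {kind} at alpha={self.alpha}: {self.rejection_rate:.3f} "
            f"(MC se {self.rejection_mc_se:.3f})",
            f"  runtime: {self.runtime_seconds:.1f}s",
        ]
        if not self.valid:
            lines.append("  WARNING: >5% replicate failures — cell flagged invalid")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _rct_estimate(cohort, level: float):
    """Two-sample comparison of the randomized arms.

    Returns (point, ci, pvalue): Welch t on means for continuous outcomes,
    risk difference with the pooled two-proportion z-test for binary.
    """
    y = pd.to_numeric(cohort.outcome, errors="coerce").to_numpy(dtype=float)
    t_mask = (cohort.data["treated"] == 1).to_numpy()
    y1, y0 = y[t_mask], y[~t_mask]
    if cohort.outcome_spec.scale == "continuous":
        point = float(y1.mean() - y0.mean())
        se = float(np.sqrt(y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0)))
        dof = len(y1) + len(y0) - 2
        tcrit = stats.t.ppf(0.5 + level / 2, dof)
        tstat = point / se if se > 0 else np.inf
        p = float(2 * stats.t.sf(abs(tstat), dof))
        return point, (point - tcrit * se, point + tcrit * se), p
    p1, p0 = y1.mean(), y0.mean()
    n1, n0 = len(y1), len(y0)
    point = float(p1 - p0)
    pbar = (y1.sum() + y0.sum()) / (n1 + n0)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z = point / se0 if se0 > 0 else 0.0
    pval = float(2 * stats.norm.sf(abs(z)))
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return point, (point - zcrit * se1, point + zcrit * se1), pval


def run_cell(
    scenario: SimulationScenario,
    n_reps: int,
    design: str = "virtual-control",
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    level: float | None = None,
) -> OpCharCell:
    """Monte-Carlo evaluation of one scenario under one design."""
    if n_reps < 100:
        raise ContractError(f"need n_reps >= 100, got {n_reps}")
    if design not in DESIGNS:
        raise ConfigurationError(f"unknown design {design!r}; expected one of {DESIGNS}")
    level = 1 - alpha if level is None else level
    truth = GroundTruth.from_scenario(scenario)
    tau = scenario.tau
    t0 = time.perf_counter()

    points, covers, rejects = [], [], []
    n_failed = 0
    for r in range(n_reps):
        try:
            if design == "virtual-control":
                training = generate_training_cohort(scenario, seed=[seed, r, 0])
                fitted = PrognosticRegression(training).fit()
                arm = generate_single_arm_cohort(scenario, seed=[seed, r, 1])
                vc = predict_virtual_controls(fitted.model, arm)
                if scenario.outcome_scale == "continuous":
                    est = estimate_effect_continuous(arm, vc, level, model=fitted.model)
                else:
                    est = estimate_effect_binary(arm, vc, level)
                point, ci, pval = est.point, est.ci, est.pvalue
            else:
                rct = generate_rct_cohort(scenario, seed=[seed, r, 2])
                point, ci, pval = _rct_estimate(rct, level)
        except Exception:
            n_failed += 1
            continue
        points.append(point)
        covers.append(ci[0] <= tau <= ci[1])
        rejects.append(pval < alpha)

    n_ok = len(points)
    pts = np.asarray(points, dtype=float)
    cov = float(np.mean(covers)) if n_ok else np.nan
    rej = float(np.mean(rejects)) if n_ok else np.nan
    return OpCharCell(
        design=design,
        n_reps=n_ok,
        n_failed=n_failed,
        true_tau=tau,
        true_r2=truth.true_r2,
        expected_bias=truth.expected_bias,
        bias=float(pts.mean() - tau) if n_ok else np.nan,
        bias_mc_se=float(pts.std(ddof=1) / np.sqrt(n_ok)) if n_ok > 1 else np.nan,
        rmse=float(np.sqrt(np.mean((pts - tau) ** 2))) if n_ok else np.nan,
        coverage=cov,
        coverage_mc_se=float(np.sqrt(cov * (1 - cov) / n_ok)) if n_ok else np.nan,
        rejection_rate=rej,
        rejection_mc_se=float(np.sqrt(rej * (1 - rej) / n_ok)) if n_ok else np.nan,
        alpha=alpha,
        level=level,
        runtime_seconds=time.perf_counter() - t0,
        valid=n_failed <= MAX_FAILURE_FRACTION * n_reps,
    )


@dataclass(frozen=True)
class R2SweepResult:
    """Power (and companions) across a grid of true prognostic R-square."""

    table: pd.DataFrame
    minimal_r2: float | None
    power_threshold: float
    monotone_within_mc: bool

    def summary(self) -> str:
        lines = ["R-square sweep:"]
        lines.append(
            self.table[["r2", "power", "power_mc_se", "coverage", "bias"]].to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            )
        )
        if self.minimal_r2 is None:
            lines.append(
                f"no grid value reaches power >= {self.power_threshold}"
            )
        else:
            lines.append(
                f"minimal R-square with power >= {self.power_threshold}: {self.minimal_r2}"
            )
        lines.append(f"power monotone in R-square (within 2 MC se): {self.monotone_within_mc}")
        return "\n".join(lines)


def r2_sweep(
    base_scenario: SimulationScenario,
    r2_grid: Sequence[float],
    n_reps: int = 500,
    seed: int = 0,
    design: str = "virtual-control",
    power_threshold: float = 0.8,
    alpha: float = DEFAULT_ALPHA,
) -> R2SweepResult:
    """Back-solve sigma for each target R-square and evaluate the cell.

    Answers "how accurate does prediction have to be" for the scenario's
    sample sizes and effect size: the report includes the smallest grid
    R-square whose power meets ``power_threshold``.
    """
    if any(not (0 < r < 1) for r in r2_grid):
        raise ConfigurationError("r2 grid values must lie in (0, 1)")
    rows = []
    for i, r2 in enumerate(r2_grid):
        cell = run_cell(
            base_scenario.with_r2(r2), n_reps, design=design, seed=seed + i, alpha=alpha
        )
        rows.append(
            {
                "r2": r2,
                "sigma": base_scenario.sigma_for_r2(r2),
                "power": cell.rejection_rate,
                "power_mc_se": cell.rejection_mc_se,
                "coverage": cell.coverage,
                "bias": cell.bias,
                "rmse": cell.rmse,
                "n_reps": cell.n_reps,
            }
        )
    table = pd.DataFrame(rows).sort_values("r2").reset_index(drop=True)
    power = table["power"].to_numpy()
    mc = table["power_mc_se"].to_numpy()
    monotone = bool(
        all(
            power[i + 1] >= power[i] - 2 * np.hypot(mc[i], mc[i + 1])
            for i in range(len(power) - 1)
        )
    )
    meets = table[table["power"] >= power_threshold]
    minimal = float(meets["r2"].iloc[0]) if len(meets) else None
    return R2SweepResult(
        table=table,
        minimal_r2=minimal,
        power_threshold=power_threshold,
        monotone_within_mc=monotone,
    )


# ---------------------------------------------------------------------------
# two-proportion power (rare-event sample-size reasoning)

_ENUM_CELL_LIMIT = 4_000_000  # max pmf-grid size for exact enumeration
_TAIL_EPS = 1e-12


def _binom_support(n: int, p: float) -> np.ndarray:
    """Support of Binomial(n, p) truncated to non-negligible mass."""
    if n <= 1000:
        return np.arange(n + 1)
    lo = int(stats.binom.ppf(_TAIL_EPS, n, p)) if p > 0 else 0
    hi = int(stats.binom.ppf(1 - _TAIL_EPS, n, p)) + 1 if p > 0 else 0
    return np.arange(max(lo - 2, 0), min(hi + 2, n) + 1)


def power_two_proportion(
    p0: float, p1: float, n_per_arm: int, alpha: float = DEFAULT_ALPHA
) -> tuple[float, str]:
    """Power of the two-sided pooled z-test comparing two proportions.

    Exact by enumeration of the joint binomial outcome grid whenever that
    grid (after truncating negligible tails) is tractable — which covers
    both small trials and rare events in large trials; otherwise the
    standard normal-approximation power formula.  Returns
    ``(power, method_tag)``.
    """
    if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
        raise ContractError("proportions must lie in [0, 1]")
    if n_per_arm < 1:
        raise ContractError("n_per_arm must be >= 1")
    n = n_per_arm
    zcrit = stats.norm.ppf(1 - alpha / 2)

    s0 = _binom_support(n, p0)
    s1 = _binom_support(n, p1)
    if len(s0) * len(s1) <= _ENUM_CELL_LIMIT:
        pmf0 = stats.binom.pmf(s0, n, p0)
        pmf1 = stats.binom.pmf(s1, n, p1)
        x0 = s0[:, None].astype(float)
        x1 = s1[None, :].astype(float)
        pooled = (x0 + x1) / (2 * n)
        var = pooled * (1 - pooled) * (2 / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, (x1 / n - x0 / n) / np.sqrt(var), 0.0)
        reject = np.abs(z) > zcrit
        power = float(pmf0 @ reject @ pmf1)
        return power, "exact-enumeration"

    pbar = (p0 + p1) / 2
    se0 = np.sqrt(2 * pbar * (1 - pbar) / n)
    se1 = np.sqrt(p0 * (1 - p0) / n + p1 * (1 - p1) / n)
    delta = p1 - p0
    power = float(
        stats.norm.sf((zcrit * se0 - delta) / se1)
        + stats.norm.cdf((-zcrit * se0 - delta) / se1)
    )
    return power, "normal-approximation"
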