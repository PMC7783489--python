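"""Virtual-control prediction and effect estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virtualcontrols import (
    Cohort,
    CovariateSchema,
    OutcomeSpec,
    PrognosticModel,
    PrognosticRegression,
    SimulationScenario,
    SingleArmComparison,
    TrainingMeta,
    Variable,
    VirtualControlSet,
    added_value_scores,
    bootstrap_propagate,
    estimate_effect_binary,
    estimate_effect_continuous,
    generate_single_arm_cohort,
    generate_training_cohort,
    poisson_binomial_pmf,
    poisson_binomial_test,
    predict_virtual_controls,
)
from virtualcontrols.exceptions import (
    ContractError,
    InsufficientDataError,
)
from conftest import make_continuous_cohort


def _linear_model(intercept, coefs, supports=None, n=100):
    variables = tuple(
        Variable(name, support=(supports or {}).get(name)) for name in coefs
    )
    return PrognosticModel(
        family="linear",
        intercept=intercept,
        coefficients=dict(coefs),
        schema=CovariateSchema(variables),
        training_meta=TrainingMeta(
            n=n, precision=0.5, param_order=("(intercept)", *coefs)
        ),
        outcome_spec=OutcomeSpec("y", "continuous"),
    )


def _logistic_model(intercept, coefs):
    m = _linear_model(intercept, coefs)
    return PrognosticModel(
        family="logistic",
        intercept=m.intercept,
        coefficients=m.coefficients,
        schema=m.schema,
        training_meta=m.training_meta,
        outcome_spec=OutcomeSpec("y", "binary"),
    )


def _treated(x, y, scale="continuous"):
    df = pd.DataFrame(
        {"id": [f"s{i}" for i in range(len(x))], "x1": x, "treated": 1, "y": y}
    )
    return Cohort(
        df, CovariateSchema((Variable("x1"),)), OutcomeSpec("y", scale)
    )


class TestPredict:
    def test_all_zero_covariates_predict_intercept(self):
        model = _linear_model(2.5, {"x1": 3.0})
        vc = predict_virtual_controls(model, _treated(np.zeros(4), np.ones(4)))
        np.testing.assert_allclose(vc.predictions.to_numpy(), 2.5)

    def test_logistic_zero_intercept_gives_half(self):
        model = _logistic_model(0.0, {"x1": 0.0})
        vc = predict_virtual_controls(
            model, _treated(np.ones(3), np.ones(3), scale="binary")
        )
        np.testing.assert_allclose(vc.predictions.to_numpy(), 0.5)

    def test_predictions_match_row_by_row_dot_product(self, fitted, treated_arm):
        vc = predict_virtual_controls(fitted.model, treated_arm)
        model = fitted.model
        for _, row in treated_arm.data.iterrows():
            expected = model.intercept + sum(
                model.coefficients[name] * row[name] for name in model.coefficients
            )
            assert vc.predictions[row["id"]] == pytest.approx(expected, abs=1e-12)

    def test_untreated_cohort_rejected(self, fitted, training_cohort):
        with pytest.raises(ContractError, match="treated"):
            predict_virtual_controls(fitted.model, training_cohort)

    def test_missing_covariates_skip_subject_with_warning(self, fitted, treated_arm):
        df = treated_arm.data.copy()
        df.loc[0, "x1"] = np.nan
        arm = Cohort(df, treated_arm.schema, treated_arm.outcome_spec)
        with pytest.warns(UserWarning, match="skipped"):
            vc = predict_virtual_controls(fitted.model, arm)
        assert vc.skipped_ids == (df.loc[0, "id"],)
        assert vc.n == arm.n - 1

    def test_extrapolation_flagged_outside_support(self):
        model = _linear_model(0.0, {"x1": 1.0}, supports={"x1": (-1.0, 1.0)})
        vc = predict_virtual_controls(model, _treated([0.0, 5.0], [0.0, 0.0]))
        assert vc.table["extrapolation"].tolist() == [False, True]
        assert vc.n_extrapolated == 1


class TestAddedValue:
    def test_observed_equal_predicted_gives_zero(self):
        model = _linear_model(0.0, {"x1": 1.0})
        arm = _treated([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        scores = added_value_scores(arm, predict_virtual_controls(model, arm))
        np.testing.assert_allclose(scores.to_numpy(), 0.0)

    def test_unit_shift_gives_unit_scores(self):
        model = _linear_model(0.0, {"x1": 1.0})
        arm = _treated([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        scores = added_value_scores(arm, predict_virtual_controls(model, arm))
        np.testing.assert_allclose(scores.to_numpy(), 1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=2,
            max_size=30,
        )
    )
    def test_mean_score_equals_difference_of_means(self, pairs):
        obs = np.array([a for a, _ in pairs])
        x = np.array([b for _, b in pairs])
        model = _linear_model(0.0, {"x1": 1.0})
        arm = _treated(x, obs)
        scores = added_value_scores(arm, predict_virtual_controls(model, arm))
        assert scores.mean() == pytest.approx(obs.mean() - x.mean(), abs=1e-9)


class TestContinuousEstimate:
    def test_zero_variance_scores_reported_as_degenerate(self):
        model = _linear_model(0.0, {"x1": 1.0})
        arm = _treated([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        est = estimate_effect_continuous(
            arm, predict_virtual_controls(model, arm), uncertainty="plugin"
        )
        assert est.point == 0.0
        assert est.pvalue == pytest.approx(1.0)
        assert est.method == "degenerate-zero-variance"

    def test_ci_matches_hand_computed_t_interval(self):
        # scores 1..5: mean 3, s = sqrt(2.5), se = 0.70711, t_4(.975) = 2.77645
        model = _linear_model(0.0, {"x1": 1.0})
        arm = _treated(np.zeros(5), [1.0, 2.0, 3.0, 4.0, 5.0])
        est = estimate_effect_continuous(
            arm, predict_virtual_controls(model, arm), uncertainty="plugin"
        )
        assert est.point == pytest.approx(3.0)
        assert est.standardized == pytest.approx(3.0 / np.sqrt(2.5), abs=1e-9)
        assert est.ci[0] == pytest.approx(1.0367, abs=2e-4)
        assert est.ci[1] == pytest.approx(4.9633, abs=2e-4)
        assert est.statistic == pytest.approx(4.2426, abs=1e-4)
        assert est.pvalue == pytest.approx(0.0132, abs=5e-4)

    def test_recovers_simulated_effect(self):
        # true effect 0.5 at prognostic R^2 = 0.6, n = 200; 200 replicates
        scn = SimulationScenario(tau=0.5, n_train=400, n_treated=200)
        points = []
        for r in range(200):
            model = PrognosticRegression(
                generate_training_cohort(scn, seed=[50, r, 0])
            ).fit().model
            arm = generate_single_arm_cohort(scn, seed=[50, r, 1])
            vc = predict_virtual_controls(model, arm)
            points.append(estimate_effect_continuous(arm, vc, model=model).point)
        pts = np.asarray(points)
        mc_se = pts.std(ddof=1) / np.sqrt(len(pts))
        assert abs(pts.mean() - 0.5) < 3 * mc_se

    def test_single_subject_is_insufficient(self):
        model = _linear_model(0.0, {"x1": 1.0})
        arm = _treated([1.0], [2.0])
        with pytest.raises(InsufficientDataError):
            estimate_effect_continuous(arm, predict_virtual_controls(model, arm))

    def test_extrapolation_count_surfaced_in_estimate(self):
        model = _linear_model(0.0, {"x1": 1.0}, supports={"x1": (-1.0, 1.0)})
        arm = _treated([0.0, 5.0, 0.5], [1.0, 2.0, 3.0])
        est = estimate_effect_continuous(
            arm, predict_virtual_controls(model, arm), uncertainty="plugin"
        )
        assert est.n_extrapolated == 1


class TestBinaryEstimate:
    def test_risk_difference_from_observed_and_predicted_rates(self):
        # assist-device configuration: predicted survival 11%, observed 69%
        n = 100
        y = np.r_[np.ones(69), np.zeros(31)]
        arm = _treated(np.zeros(n), y, scale="binary")
        vc = VirtualControlSet(
            table=pd.DataFrame(
                {"id": arm.ids, "prediction": np.full(n, 0.11), "extrapolation": False}
            ),
            family="logistic",
            model_version=1,
        )
        est = estimate_effect_binary(arm, vc)
        assert est.point == pytest.approx(0.58, abs=1e-12)
        assert est.risk_ratio == pytest.approx(0.69 / 0.11, abs=1e-9)
        assert est.pvalue < 1e-10

    def test_null_configuration_gives_zero_z(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        arm = _treated(np.zeros(100), y, scale="binary")
        vc = VirtualControlSet(
            table=pd.DataFrame(
                {"id": arm.ids, "prediction": np.full(100, 0.3), "extrapolation": False}
            ),
            family="logistic",
            model_version=1,
        )
        est = estimate_effect_binary(arm, vc)
        assert est.point == pytest.approx(0.0, abs=1e-12)
        assert abs(est.statistic) < 1e-10

    def test_probability_outside_unit_interval_rejected(self):
        arm = _treated([0.0, 1.0], [0.0, 1.0], scale="binary")
        vc = VirtualControlSet(
            table=pd.DataFrame(
                {"id": arm.ids, "prediction": [0.5, 1.2], "extrapolation": False}
            ),
            family="logistic",
            model_version=1,
        )
        with pytest.raises(ContractError):
            estimate_effect_binary(arm, vc)

    def test_risk_difference_invariant_to_subject_order(self):
        rng = np.random.default_rng(4)
        y = (rng.random(30) < 0.4).astype(float)
        p = rng.random(30) * 0.5
        arm = _treated(np.zeros(30), y, scale="binary")
        vc = VirtualControlSet(
            table=pd.DataFrame({"id": arm.ids, "prediction": p, "extrapolation": False}),
            family="logistic",
            model_version=1,
        )
        est1 = estimate_effect_binary(arm, vc)
        perm = rng.permutation(30)
        arm2 = Cohort(
            arm.data.iloc[perm].reset_index(drop=True), arm.schema, arm.outcome_spec
        )
        vc2 = VirtualControlSet(
            table=vc.table.iloc[perm].reset_index(drop=True),
            family="logistic",
            model_version=1,
        )
        est2 = estimate_effect_binary(arm2, vc2)
        assert est1.point == pytest.approx(est2.point, abs=1e-15)
        assert est1.pvalue == pytest.approx(est2.pvalue, abs=1e-12)


class TestPoissonBinomial:
    def test_pmf_matches_exhaustive_enumeration_n10(self):
        rng = np.random.default_rng(2)
        ps = rng.random(10)
        pmf = poisson_binomial_pmf(ps)
        brute = np.zeros(11)
        for bits in itertools.product([0, 1], repeat=10):
            w = np.prod([p if b else 1 - p for p, b in zip(ps, bits)])
            brute[sum(bits)] += w
        np.testing.assert_allclose(pmf, brute, atol=1e-12)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_normal_approximation_agrees_with_exact_at_n10(self):
        rng = np.random.default_rng(3)
        ps = 0.2 + 0.6 * rng.random(10)
        for k in range(11):
            _, p_exact, tag = poisson_binomial_test(k, ps)
            assert tag == "poisson-binomial-exact"
            mu, var = ps.sum(), (ps * (1 - ps)).sum()
            from scipy import stats as sps

            # continuity-corrected normal tail, as used above n = 20
            zc = max(abs(k - mu) - 0.5, 0.0) / np.sqrt(var)
            p_norm = min(1.0, 2 * sps.norm.sf(zc))
            # the approximation is crude at n=10; agreement is loose
            assert p_norm == pytest.approx(p_exact, abs=0.12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=15))
    def test_pmf_is_a_distribution(self, ps):
        pmf = poisson_binomial_pmf(ps)
        assert len(pmf) == len(ps) + 1
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (pmf >= -1e-15).all()


class TestBootstrap:
    def test_same_seed_reproduces_ci(self, training_cohort, treated_arm):
        a = bootstrap_propagate(training_cohort, treated_arm, B=100, seed=42)
        b = bootstrap_propagate(training_cohort, treated_arm, B=100, seed=42)
        assert a.ci == b.ci
        assert a.uncertainty_mode == "bootstrap-propagated"

    def test_replicate_bookkeeping(self, small_scenario):
        scn = SimulationScenario(n_train=50, n_treated=50)
        training = generate_training_cohort(scn, seed=8)
        arm = generate_single_arm_cohort(scn, seed=9)
        est = bootstrap_propagate(training, arm, B=100, seed=1)
        assert est.extras["n_replicates"] + est.extras["n_failed_replicates"] == 100

    def test_too_few_replicates_rejected(self, training_cohort, treated_arm):
        with pytest.raises(ContractError, match="B >= 100"):
            bootstrap_propagate(training_cohort, treated_arm, B=10, seed=0)

    def test_bootstrap_ci_tends_wider_than_plugin(self):
        # training uncertainty can only add variance: average over scenarios
        wider = 0
        total = 0
        for s in range(50):
            scn = SimulationScenario(n_train=60, n_treated=40)
            training = generate_training_cohort(scn, seed=[700, s, 0])
            arm = generate_single_arm_cohort(scn, seed=[700, s, 1])
            model = PrognosticRegression(training).fit().model
            vc = predict_virtual_controls(model, arm)
            plugin = estimate_effect_continuous(arm, vc, uncertainty="plugin")
            boot = bootstrap_propagate(training, arm, B=100, seed=s)
            total += 1
            if (boot.ci[1] - boot.ci[0]) >= (plugin.ci[1] - plugin.ci[0]):
                wider += 1
        assert wider / total > 0.5


def test_single_arm_comparison_facade(fitted, treated_arm):
    results = SingleArmComparison(treated_arm, fitted).fit()
    assert results.estimate.uncertainty_mode == "analytic-propagated"
    assert results.ci[0] <= results.point <= results.ci[1]
    assert "Virtual-control comparison" in results.summary()
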