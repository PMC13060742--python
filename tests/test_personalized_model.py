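import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from matppm.errors import DataError, ParameterError
from matppm.personalized_model import (
    CoefficientSet,
    ModelSpec,
    binomial_log_likelihood,
    build_design,
    fit_binomial_glm,
    fit_design,
    fit_personalized,
    predict_probability,
)
from matppm.similarity import ScalingSpec
from matppm.study_data import SubtaskOutcome
from matppm.synthetic_data import (
    PopulationConfig,
    homogeneous_cohort,
    make_truth,
    simulate_outcomes,
    simulate_profiles,
)


@pytest.fixture(scope="module")
def cohort():
    cfg = PopulationConfig(n_participants=25, seed=17)
    profiles = simulate_profiles(cfg)
    truth = make_truth(profiles, [{"cognitive_score": 0.5, "age": -0.3}], seed=17)
    outcomes = simulate_outcomes(profiles, truth, cfg)
    return profiles, outcomes


class TestModelSpec:
    def test_exactly_one_vision_score(self):
        smat = ModelSpec(vision_variant="smat").predictor_fields
        dltv = ModelSpec(vision_variant="dltv").predictor_fields
        assert "smat_vision_score" in smat and "dltv_summary_vision_score" not in smat
        assert "dltv_summary_vision_score" in dltv and "smat_vision_score" not in dltv

    def test_age_flag_reproduces_literal_equations(self):
        assert "age" in ModelSpec().predictor_fields
        assert "age" not in ModelSpec(include_age=False).predictor_fields

    def test_reference_must_be_in_taxonomy(self):
        with pytest.raises(ParameterError):
            ModelSpec(subtask_reference="ZZ")


class TestBuildDesign:
    def test_one_hot_minus_reference(self, cohort, smat_spec):
        profiles, _ = cohort
        lookup = {p.participant_id: p for p in profiles}
        pid = profiles[0].participant_id
        outcomes = [
            SubtaskOutcome(pid, "D01", "A1", 4, 1),
            SubtaskOutcome(pid, "D01", "A2", 2, 0),
            SubtaskOutcome(profiles[1].participant_id, "D02", "A2", 3, 1),
        ]
        design = build_design(outcomes, lookup, smat_spec, ScalingSpec.fit(profiles, "smat"))
        subtask_cols = [c for c in design.columns if c.startswith("subtask[")]
        assert subtask_cols == ["subtask[A2]"]
        assert design.reference_level == "A1"

    def test_response_and_weight_are_counts(self, cohort, smat_spec):
        profiles, _ = cohort
        lookup = {p.participant_id: p for p in profiles}
        outcomes = [SubtaskOutcome(profiles[0].participant_id, "D01", "A1", 4, 1),
                    SubtaskOutcome(profiles[1].participant_id, "D01", "A2", 2, 2)]
        design = build_design(outcomes, lookup, smat_spec, ScalingSpec.fit(profiles, "smat"))
        assert design.successes.tolist() == [3.0, 0.0]
        assert design.trials.tolist() == [4.0, 2.0]
        assert np.array_equal(design.weights, design.trials)

    def test_same_participant_rows_share_covariates(self, cohort, smat_spec):
        profiles, _ = cohort
        lookup = {p.participant_id: p for p in profiles}
        pid = profiles[0].participant_id
        outcomes = [SubtaskOutcome(pid, "D01", "A1", 2, 0),
                    SubtaskOutcome(pid, "D02", "B1", 3, 1),
                    SubtaskOutcome(profiles[2].participant_id, "D01", "B1", 1, 0)]
        design = build_design(outcomes, lookup, smat_spec, ScalingSpec.fit(profiles, "smat"))
        k = sum(1 for c in design.columns if not c.startswith("subtask["))
        assert np.array_equal(design.X[0, :k], design.X[1, :k])


class TestFitBinomialGlm:
    def test_intercept_only_closed_form(self):
        X = np.ones((2, 1))
        fit = fit_binomial_glm(X, successes=[3, 1], trials=[4, 4],
                               columns=["intercept"])
        assert fit.values[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.converged and fit.penalty_used == 0.0

    def test_symmetric_half_successes_give_zero_slopes(self):
        X = np.column_stack([np.ones(4), [-1.0, -0.5, 0.5, 1.0]])
        fit = fit_binomial_glm(X, successes=[2, 2, 2, 2], trials=[4, 4, 4, 4],
                               columns=["intercept", "x"])
        assert np.allclose(fit.values, 0.0, atol=1e-8)

    def test_loglik_matches_direct_optimizer_oracle(self, rng):
        # derivative-free oracle on random small instances
        for _ in range(40):
            rows, cols = int(rng.integers(2, 7)), int(rng.integers(1, 4))
            X = np.column_stack([np.ones(rows), rng.normal(size=(rows, cols - 1))]) \
                if cols > 1 else np.ones((rows, 1))
            n = rng.integers(1, 5, size=rows)
            p = expit(rng.normal(0, 1, size=rows))
            s = rng.binomial(n, p)
            fit = fit_binomial_glm(X, s, n)
            if fit.penalty_used > 0:
                continue  # separated instance; penalized objective differs
            oracle = minimize(
                lambda b: -binomial_log_likelihood(b, X, s, n),
                np.zeros(cols), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            assert fit.log_likelihood >= -oracle.fun - 1e-6

    def test_weight_splitting_invariance(self, rng):
        # a row with n_present=2 equals two rows with n_present=1
        X = np.column_stack([np.ones(3), rng.normal(size=3)])
        s, n = np.array([1, 2, 3]), np.array([2, 2, 4])
        fit_a = fit_binomial_glm(X, s, n)
        X2 = np.repeat(X, n.astype(int), axis=0)
        ones = np.ones(int(n.sum()), dtype=int)
        s2 = np.concatenate([[1, 0], [1, 1], [1, 1, 1, 0]])
        fit_b = fit_binomial_glm(X2, s2, ones)
        assert np.allclose(fit_a.values, fit_b.values, atol=1e-8)

    def test_separation_triggers_ridge_fallback(self):
        # perfectly separated: success iff x > 0
        X = np.column_stack([np.ones(4), [-2.0, -1.0, 1.0, 2.0]])
        fit = fit_binomial_glm(X, successes=[0, 0, 1, 1], trials=[1, 1, 1, 1],
                               columns=["intercept", "x"])
        assert fit.penalty_used > 0.0

    def test_nonconverged_implies_penalty_recorded(self):
        with pytest.raises(ParameterError):
            CoefficientSet(columns=("intercept",), values=np.zeros(1),
                           converged=False, iterations=5, penalty_used=0.0,
                           log_likelihood=0.0)

    def test_agrees_with_statsmodels_glm(self, cohort, smat_spec):
        # independent cross-check of the full design + fit path
        sm = pytest.importorskip("statsmodels.api")
        profiles, outcomes = cohort
        lookup = {p.participant_id: p for p in profiles}
        scaling = ScalingSpec.fit(profiles, "smat")
        design = build_design(outcomes, lookup, smat_spec, scaling)
        fit = fit_design(design, smat_spec)
        assert fit.penalty_used == 0.0
        resp = np.column_stack([design.successes, design.trials - design.successes])
        ref = sm.GLM(resp, design.X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.values, ref.params, atol=1e-6)


class TestPredictProbability:
    def make_coeffs(self, columns, values):
        return CoefficientSet(columns=tuple(columns), values=np.asarray(values, float),
                              converged=True, iterations=1, penalty_used=0.0,
                              log_likelihood=0.0, reference_level="A1")

    def test_all_zero_coefficients_give_half(self, cohort, smat_spec):
        profiles, _ = cohort
        scaling = ScalingSpec.fit(profiles, "smat")
        cols = ["intercept"] + list(smat_spec.predictor_fields)
        coeffs = self.make_coeffs(cols, np.zeros(len(cols)))
        p = predict_probability(coeffs, profiles[0], "A1", smat_spec, scaling)
        assert p == pytest.approx(0.5)

    def test_log3_intercept_gives_three_quarters(self, cohort, smat_spec):
        profiles, _ = cohort
        scaling = ScalingSpec.fit(profiles, "smat")
        coeffs = self.make_coeffs(["intercept"], [math.log(3.0)])
        p = predict_probability(coeffs, profiles[0], "A1", smat_spec, scaling)
        assert p == pytest.approx(0.75)

    def test_unseen_subtask_predicts_at_reference(self, cohort, smat_spec, caplog):
        profiles, _ = cohort
        scaling = ScalingSpec.fit(profiles, "smat")
        coeffs = self.make_coeffs(["intercept", "subtask[A2]"], [0.2, 1.0])
        at_ref = predict_probability(coeffs, profiles[0], "A1", smat_spec, scaling)
        unseen = predict_probability(coeffs, profiles[0], "U1", smat_spec, scaling)
        assert unseen == at_ref

    def test_probability_strictly_inside_unit_interval(self, cohort, smat_spec, rng):
        profiles, _ = cohort
        scaling = ScalingSpec.fit(profiles, "smat")
        cols = ["intercept"] + list(smat_spec.predictor_fields)
        for _ in range(20):
            coeffs = self.make_coeffs(cols, rng.normal(0, 3, len(cols)))
            p = predict_probability(coeffs, profiles[0], "A1", smat_spec, scaling)
            assert 0.0 < p < 1.0


class TestFitPersonalized:
    def test_m_one_identical_for_every_target(self, cohort, smat_spec):
        profiles, outcomes = cohort
        targets = profiles[:2]
        pool = profiles[2:]
        pool_ids = {p.participant_id for p in pool}
        pool_outcomes = [o for o in outcomes if o.participant_id in pool_ids]
        scaling = ScalingSpec.fit(pool, "smat")
        fits = [fit_personalized(t, pool, pool_outcomes, 1.0, smat_spec, scaling)
                for t in targets]
        assert np.array_equal(fits[0].values, fits[1].values)
        assert set(fits[0].trained_on) == pool_ids

    def test_matched_count_follows_ceil_rule(self, cohort, smat_spec):
        profiles, outcomes = cohort
        target = profiles[0]
        pool = profiles[1:]   # 24 candidates
        pool_ids = {p.participant_id for p in pool}
        pool_outcomes = [o for o in outcomes if o.participant_id in pool_ids]
        fit = fit_personalized(target, pool, pool_outcomes, 0.25, smat_spec)
        assert len(fit.trained_on) == math.ceil(0.25 * 24)
        assert fit.m_used == 0.25

    def test_empty_matched_outcomes_raise(self, cohort, smat_spec):
        profiles, _ = cohort
        with pytest.raises(DataError):
            fit_personalized(profiles[0], profiles[1:], [], 0.5, smat_spec)


class TestCoefficientSerialization:
    def test_text_round_trip(self, cohort, smat_spec):
        profiles, outcomes = cohort
        fit = fit_personalized(profiles[0], profiles[1:],
                               [o for o in outcomes
                                if o.participant_id != profiles[0].participant_id],
                               0.5, smat_spec)
        again = CoefficientSet.from_text(fit.to_text())
        assert again.columns == fit.columns
        assert np.array_equal(again.values, fit.values)
        assert again.trained_on == fit.trained_on
        assert again.m_used == fit.m_used
        assert again.penalty_used == fit.penalty_used


class TestParameterRecovery:
    def test_wald_band_coverage_on_large_cohort(self):
        """All coefficients (incl. subtask effects) sit inside 95% Wald bands
        in the large majority of replicates."""
        hits, total = 0, 0
        for seed in range(5):
            profiles, outcomes, truth = homogeneous_cohort(2000, seed=100 + seed)
            spec = ModelSpec("smat")
            lookup = {p.participant_id: p for p in profiles}
            design = build_design(outcomes, lookup, spec, truth.scaling)
            fit = fit_design(design, spec)
            eta = design.X @ fit.values
            w = design.trials * expit(eta) * (1 - expit(eta))
            cov = np.linalg.inv((design.X * w[:, None]).T @ design.X)
            se = np.sqrt(np.diag(cov))
            tr = truth.coefficient_sets[0]
            for j, c in enumerate(fit.columns):
                if c not in tr.columns:
                    continue
                total += 1
                hits += abs(fit.coef(c) - tr.coef(c)) <= 1.96 * se[j]
        assert hits / total >= 0.90
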