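import numpy as np
import pytest
import scipy.stats

from matppm.errors import DataError, ParameterError
from matppm.evaluation import (
    DEFAULT_M_GRID,
    compare_wilcoxon,
    cross_validate_m,
    holdout_evaluate,
    make_folds,
    naive_baseline_probability,
    subtask_squared_error,
)
from matppm.personalized_model import ModelSpec, build_design, fit_design, predict_from_covariates, participant_covariates
from matppm.similarity import ScalingSpec
from matppm.synthetic_data import homogeneous_cohort, study_fixture


class TestSubtaskSquaredError:
    @pytest.mark.parametrize("p,n,s,expected", [
        (0.5, 4, 2, 0.0),
        (1.0, 4, 3, 1.0),
        (0.0, 2, 2, 4.0),
        (0.75, 4, 1, 4.0),
    ])
    def test_count_scale_examples(self, p, n, s, expected):
        assert subtask_squared_error(p, n, s) == pytest.approx(expected)

    def test_probability_domain_enforced(self):
        with pytest.raises(ParameterError):
            subtask_squared_error(1.2, 4, 2)


class TestMakeFolds:
    def test_117_participants_into_9_folds_of_13(self):
        ids = [f"P{i:04d}" for i in range(117)]
        folds = make_folds(ids, k=9, seed=0)
        assert [len(f) for f in folds] == [13] * 9
        assert sorted(x for f in folds for x in f) == sorted(ids)

    def test_96_participants_into_8_folds_of_12(self):
        ids = [f"P{i:04d}" for i in range(96)]
        folds = make_folds(ids, k=8, seed=0)
        assert [len(f) for f in folds] == [12] * 8

    def test_sizes_differ_by_at_most_one(self):
        folds = make_folds([f"P{i}" for i in range(20)], k=3, seed=1)
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_deterministic_under_seed(self):
        ids = [f"P{i}" for i in range(30)]
        assert make_folds(ids, 5, seed=42) == make_folds(ids, 5, seed=42)
        assert make_folds(ids, 5, seed=42) != make_folds(ids, 5, seed=43)

    def test_invalid_k_rejected(self):
        with pytest.raises(ParameterError):
            make_folds(["a", "b", "c"], k=1, seed=0)
        with pytest.raises(ParameterError):
            make_folds(["a", "b", "c"], k=4, seed=0)


class TestNaiveBaseline:
    def test_all_successes(self):
        assert naive_baseline_probability([2, 3], [2, 3]) == 1.0

    def test_worked_example(self):
        assert naive_baseline_probability([2, 3], [2, 4]) == pytest.approx(0.8)

    def test_all_failures(self):
        assert naive_baseline_probability([0, 0], [1, 1]) == 0.0

    def test_closed_form_matches_grid_search_oracle(self, rng):
        grid = np.linspace(0.0, 1.0, 10_001)
        for _ in range(300):
            k = int(rng.integers(1, 9))
            n = rng.integers(1, 6, size=k)
            s = rng.binomial(n, rng.uniform(0.3, 1.0))
            closed = naive_baseline_probability(s, n)
            sse = ((s[None, :] - grid[:, None] * n[None, :]) ** 2).sum(axis=1)
            assert abs(closed - grid[np.argmin(sse)]) <= 1e-4

    def test_least_squares_optimality(self, rng):
        n = rng.integers(1, 5, size=12)
        s = rng.binomial(n, 0.8)
        p_star = naive_baseline_probability(s, n)
        best = np.sum((s - p_star * n) ** 2)
        for p in np.linspace(0, 1, 101):
            assert best <= np.sum((s - p * n) ** 2) + 1e-9


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning):
            assert compare_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_three_positive_differences_exact(self):
        # exact two-sided enumeration of the 2^3 sign patterns
        assert compare_wilcoxon([2.0, 4.0, 6.0], [1.0, 2.0, 3.0]) == pytest.approx(0.25)

    def test_shift_invariance(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        assert compare_wilcoxon(a, b) == pytest.approx(compare_wilcoxon(a + 5, b + 5))

    def test_matches_scipy_exact(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        ref = scipy.stats.wilcoxon(a, b, zero_method="wilcox", method="exact").pvalue
        assert compare_wilcoxon(a, b) == pytest.approx(float(ref))


@pytest.fixture(scope="module")
def cv_result():
    profiles, outcomes, _ = homogeneous_cohort(36, seed=2)
    spec = ModelSpec("smat")
    result = cross_validate_m(profiles, outcomes, spec,
                              m_grid=[0.5, 1.0], k=4, seed=2)
    return profiles, outcomes, spec, result


class TestCrossValidation:
    def test_default_grid_has_17_values(self):
        assert len(DEFAULT_M_GRID) == 17
        assert DEFAULT_M_GRID[0] == 0.20 and DEFAULT_M_GRID[-1] == 1.00

    def test_m1_column_equals_independent_global_fit(self, cv_result):
        """The m=1.0 column must be bit-identical to a global model fitted
        per fold outside the CV machinery."""
        profiles, outcomes, spec, result = cv_result
        folds = make_folds([p.participant_id for p in profiles], k=4, seed=2)
        for f, test_ids in enumerate(folds):
            test_set = set(test_ids)
            train_profiles = [p for p in profiles if p.participant_id not in test_set]
            train_outcomes = [o for o in outcomes if o.participant_id not in test_set]
            scaling = ScalingSpec.fit(train_profiles, "smat")
            lookup = {p.participant_id: p for p in train_profiles}
            fit = fit_design(build_design(train_outcomes, lookup, spec, scaling), spec)
            errors = []
            for pid in test_ids:
                target = next(p for p in profiles if p.participant_id == pid)
                cov = participant_covariates(target, spec, scaling)
                for o in outcomes:
                    if o.participant_id != pid:
                        continue
                    p_hat = predict_from_covariates(fit, cov, o.subtask_code, spec)
                    errors.append((p_hat * o.n_present - o.n_success) ** 2)
            assert result.column(1.0)[f] == np.mean(errors)

    def test_tuning_result_invariants(self, cv_result):
        _, _, _, result = cv_result
        assert result.per_fold_mse.shape == (4, 2)
        assert np.allclose(result.mean_mse_per_m, result.per_fold_mse.mean(axis=0))
        best = result.m_grid[int(np.argmin(result.mean_mse_per_m))]
        assert result.optimal_m == best

    def test_determinism(self):
        profiles, outcomes, _ = homogeneous_cohort(24, seed=5)
        spec = ModelSpec("smat")
        a = cross_validate_m(profiles, outcomes, spec, m_grid=[0.5, 1.0], k=3, seed=9)
        b = cross_validate_m(profiles, outcomes, spec, m_grid=[0.5, 1.0], k=3, seed=9)
        assert np.array_equal(a.per_fold_mse, b.per_fold_mse)
        assert a.optimal_m == b.optimal_m


class TestHoldout:
    def test_cohort_overlap_rejected(self, small_cohort, smat_spec):
        profiles, outcomes, _ = small_cohort
        with pytest.raises(DataError):
            holdout_evaluate(profiles, outcomes, profiles, outcomes, smat_spec, m=1.0)

    def test_report_fields_and_naive_consistency(self, fixture_bundle, smat_spec):
        fx = fixture_bundle
        rep = holdout_evaluate(fx.train_profiles, fx.train_outcomes,
                               fx.test_profiles, fx.test_outcomes, smat_spec, m=0.5)
        assert rep.n_test_rows == len(fx.test_outcomes)
        expected_naive = naive_baseline_probability(
            [o.n_success for o in fx.train_outcomes],
            [o.n_present for o in fx.train_outcomes])
        assert rep.naive_probability == expected_naive
        assert rep.personalized_mse >= 0 and rep.global_mse >= 0
        assert len(rep.models) == len(fx.test_profiles)
        for coeffs in rep.models.values():
            assert coeffs.m_used == 0.5

    def test_near_deterministic_truth_gives_near_zero_mse(self):
        # simulated outcomes with p ~ 1: predictions approach the truth
        profiles, outcomes, truth = homogeneous_cohort(
            60, seed=3, slopes={}, target_mean_success=None)
        # force near-certain success by refitting truth with a huge intercept
        from matppm.synthetic_data import PopulationConfig, make_truth, simulate_outcomes
        cfg = PopulationConfig(n_participants=60, seed=3)
        truth = make_truth(profiles, [{}], seed=3, subtask_effect_sd=0.0,
                           target_mean_success=None, intercept=30.0)
        outcomes = simulate_outcomes(profiles, truth, cfg)
        assert all(o.n_failed == 0 for o in outcomes)
        train, test = profiles[:40], profiles[40:]
        train_ids = {p.participant_id for p in train}
        rep = holdout_evaluate(train,
                               [o for o in outcomes if o.participant_id in train_ids],
                               test,
                               [o for o in outcomes if o.participant_id not in train_ids],
                               ModelSpec("smat"), m=1.0)
        assert rep.personalized_mse < 0.05
        assert rep.personalized_mse == rep.global_mse
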