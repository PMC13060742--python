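"""Model evaluation: count-scale MSE, CV tuning of m, baselines, holdout.

The error metric is the squared error in predicting the number of successful
attempts at a subtask, ``(p_hat * n_present - n_success)^2``, averaged over
all (participant, device, subtask) rows — a regression view of the problem
rather than a classification one. Predicted success counts are deliberately
not rounded before squaring.

Cross-validation is participant-level: each participant's rows sit in exactly
one test fold and never enter that participant's own training design. For
each fold and each matching proportion m on the grid (default 0.20 to 1.00 in
steps of 0.05), every test participant receives a personalized fit on their
matched subset of the training folds; m = 1.0 is the global, nonpersonalized
model. The optimal m minimizes the fold-averaged MSE, smallest m on ties.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from .errors import DataError, FitError, ParameterError
from .personalized_model import (
    CoefficientSet,
    ModelSpec,
    build_design,
    fit_design,
    participant_covariates,
    predict_from_covariates,
)
from .similarity import ScalingSpec, encode_cohort, matched_subset_size, rank_candidates
from .study_data import ParticipantProfile, SubtaskOutcome

log = logging.getLogger(__name__)

#: m = 0.20, 0.25, ..., 1.00 — 17 values.
DEFAULT_M_GRID: tuple[float, ...] = tuple(
    round(0.20 + 0.05 * j, 2) for j in range(17)
)


def subtask_squared_error(p_hat: float, n_present: int, n_success: int) -> float:
    """Squared error on the count scale: (p_hat * n_present - n_success)^2."""
    if not (0.0 <= p_hat <= 1.0):
        raise ParameterError(f"p_hat must lie in [0, 1], got {p_hat}")
    if not (0 <= n_success <= n_present):
        raise ParameterError("n_success must lie in [0, n_present]")
    return (p_hat * n_present - n_success) ** 2


def make_folds(participant_ids: Sequence[str], k: int, seed: int) -> list[list[str]]:
    """Random participant-level partition into k folds of near-equal size.

    Fold sizes differ by at most one; the split is reproducible from the seed
    (ids are sorted before shuffling so input order never matters).
    """
    ids = sorted(participant_ids)
    if len(set(ids)) != len(ids):
        raise ParameterError("participant ids must be unique")
    if k < 2 or k > len(ids):
        raise ParameterError(f"k must lie in [2, n_participants], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return [sorted(chunk) for chunk in
            (list(a) for a in np.array_split(np.array(shuffled, dtype=object), k))]


def naive_baseline_probability(n_success_vector: Sequence[int],
                               n_present_vector: Sequence[int]) -> float:
    """Constant success probability minimizing count-scale squared error.

    Closed form ``sum(s_i * n_i) / sum(n_i^2)`` (the least-squares solution of
    ``s_i ~ p * n_i``), clipped to [0, 1].
    """
    s = np.asarray(n_success_vector, dtype=float)
    n = np.asarray(n_present_vector, dtype=float)
    if s.shape != n.shape or s.size < 1:
        raise ParameterError("success and attempt vectors must be same nonzero length")
    if np.any(n < 0) or np.any(s < 0) or np.any(s > n):
        raise ParameterError("counts must satisfy 0 <= s_i <= n_i")
    denom = float(np.sum(n * n))
    if denom == 0.0:
        raise DataError("all attempt counts are zero; naive probability undefined")
    p = float(np.sum(s * n)) / denom
    return min(1.0, max(0.0, p))


def compare_wilcoxon(per_fold_mse_a: Sequence[float],
                     per_fold_mse_b: Sequence[float]) -> float:
    """Paired two-sided Wilcoxon signed-rank p-value between per-fold MSEs.

    Exact null distribution for n <= 25 pairs (normal approximation beyond, or
    when ties among nonzero differences force it); zero differences are
    dropped before ranking. All-zero differences degenerate to p = 1.0 with a
    warning.
    """
    a = np.asarray(per_fold_mse_a, dtype=float)
    b = np.asarray(per_fold_mse_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ParameterError("need equal-length paired vectors with at least 3 folds")
    d = a - b
    if np.all(d == 0.0):
        warnings.warn("all paired differences are zero; Wilcoxon test is degenerate",
                      stacklevel=2)
        return 1.0
    method = "exact" if np.count_nonzero(d) <= 25 else "approx"
    try:
        res = scipy.stats.wilcoxon(a, b, zero_method="wilcox",
                                   alternative="two-sided", method=method)
    except ValueError:
        res = scipy.stats.wilcoxon(a, b, zero_method="wilcox",
                                   alternative="two-sided", method="approx")
    return float(res.pvalue)


@dataclass
class FailedFit:
    fold: int
    m: float
    participant_id: str
    reason: str


@dataclass
class TuningResult:
    """Per-m, per-fold MSE table from the CV study plus the optimal m."""

    m_grid: tuple[float, ...]
    per_fold_mse: np.ndarray            # shape (k, len(m_grid)); NaN = unfittable
    mean_mse_per_m: np.ndarray
    optimal_m: float
    k: int
    seed: int
    variant: str
    naive_mse_per_fold: np.ndarray | None = None
    failed_fits: list[FailedFit] = field(default_factory=list)

    def column(self, m: float) -> np.ndarray:
        """Per-fold MSEs for one m value."""
        for j, mj in enumerate(self.m_grid):
            if math.isclose(mj, m):
                return self.per_fold_mse[:, j]
        raise ParameterError(f"m={m} not on the tuning grid")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.per_fold_mse,
                          columns=[f"m={m:.2f}" for m in self.m_grid])
        df.insert(0, "fold", np.arange(self.k))
        if self.naive_mse_per_fold is not None:
            df["naive"] = self.naive_mse_per_fold
        return df


def _validate_m_grid(m_grid: Sequence[float]) -> tuple[float, ...]:
    grid = tuple(float(m) for m in m_grid)
    if not grid:
        raise ParameterError("m grid must be nonempty")
    for m in grid:
        if not (0.0 < m <= 1.0):
            raise ParameterError(f"matching proportion m must lie in (0, 1], got {m}")
    if list(grid) != sorted(grid):
        raise ParameterError("m grid must be ascending")
    return grid


def _fit_matched(matched_ids, outcomes, lookup, spec, scaling, fit_kwargs):
    matched_set = set(matched_ids)
    subset = [o for o in outcomes if o.participant_id in matched_set]
    if not subset:
        raise DataError("matched subset has no outcome rows")
    design = build_design(subset, lookup, spec, scaling)
    return fit_design(design, spec, **fit_kwargs)


def cross_validate_m(profiles: Sequence[ParticipantProfile],
                     outcomes: Sequence[SubtaskOutcome],
                     spec: ModelSpec,
                     m_grid: Sequence[float] = DEFAULT_M_GRID,
                     k: int = 9,
                     seed: int = 0,
                     **fit_kwargs) -> TuningResult:
    """k-fold CV over the matching-proportion grid.

    Within a fold, fits are cached on the matched participant set, so the
    m = 1.0 column is computed from exactly one global fit per fold and equals
    an independently fitted global model bit-for-bit. Unfittable cells are
    recorded and excluded; the optimal m is chosen over complete columns only.
    """
    grid = _validate_m_grid(m_grid)
    ids = [p.participant_id for p in profiles]
    folds = make_folds(ids, k, seed)
    by_pid: dict[str, list[SubtaskOutcome]] = {}
    for o in outcomes:
        by_pid.setdefault(o.participant_id, []).append(o)
    profile_by_id = {p.participant_id: p for p in profiles}

    per_fold = np.full((k, len(grid)), np.nan)
    naive_fold = np.full(k, np.nan)
    failures: list[FailedFit] = []

    for f, test_ids in enumerate(folds):
        test_set = set(test_ids)
        train_profiles = [p for p in profiles if p.participant_id not in test_set]
        train_outcomes = [o for o in outcomes if o.participant_id not in test_set]
        scaling = ScalingSpec.fit(train_profiles, spec.vision_variant,
                                  spec.include_mped_routine)
        cand_ids, cand_mat = encode_cohort(train_profiles, spec.vision_variant, scaling)
        lookup = {p.participant_id: p for p in train_profiles}

        if train_outcomes:
            naive_p = naive_baseline_probability(
                [o.n_success for o in train_outcomes],
                [o.n_present for o in train_outcomes])
        else:
            naive_p = None

        fit_cache: dict[frozenset, CoefficientSet | None] = {}
        sq_errors: list[list[float]] = [[] for _ in grid]
        naive_errors: list[float] = []

        for pid in test_ids:
            rows = by_pid.get(pid, [])
            if not rows:
                continue
            target = profile_by_id[pid]
            tvec = scaling.transform_profiles([target])[0]
            order = rank_candidates(tvec, cand_mat, cand_ids)
            cov = participant_covariates(target, spec, scaling)
            if naive_p is not None:
                naive_errors += [subtask_squared_error(naive_p, o.n_present, o.n_success)
                                 for o in rows]
            for mi, m in enumerate(grid):
                matched = order[:matched_subset_size(m, len(order))]
                key = frozenset(matched)
                if key in fit_cache:
                    coeffs = fit_cache[key]
                else:
                    try:
                        coeffs = _fit_matched(matched, train_outcomes, lookup,
                                              spec, scaling, fit_kwargs)
                    except (FitError, DataError) as exc:
                        coeffs = None
                        failures.append(FailedFit(f, m, pid, str(exc)))
                        log.warning("fold %d m=%.2f target %s: unfittable (%s)",
                                    f, m, pid, exc)
                    fit_cache[key] = coeffs
                if coeffs is None:
                    if not any(fl.fold == f and fl.m == m and fl.participant_id == pid
                               for fl in failures):
                        failures.append(FailedFit(f, m, pid, "cached unfittable subset"))
                    continue
                p_by_code: dict[str, float] = {}
                for o in rows:
                    p_hat = p_by_code.get(o.subtask_code)
                    if p_hat is None:
                        p_hat = predict_from_covariates(coeffs, cov, o.subtask_code, spec)
                        p_by_code[o.subtask_code] = p_hat
                    sq_errors[mi].append(
                        subtask_squared_error(p_hat, o.n_present, o.n_success))

        for mi in range(len(grid)):
            if sq_errors[mi]:
                per_fold[f, mi] = float(np.mean(sq_errors[mi]))
        if naive_errors:
            naive_fold[f] = float(np.mean(naive_errors))

    mean_per_m = per_fold.mean(axis=0)      # NaN-poisoned for incomplete columns
    complete = np.isfinite(mean_per_m)
    if not complete.any():
        raise DataError("no complete m column; cross-validation produced no optimum")
    best = np.nanargmin(np.where(complete, mean_per_m, np.inf))
    n_failed = len(failures)
    if n_failed:
        log.info("cross_validate_m: %d unfittable cells excluded", n_failed)
    return TuningResult(
        m_grid=grid,
        per_fold_mse=per_fold,
        mean_mse_per_m=mean_per_m,
        optimal_m=float(grid[best]),
        k=k,
        seed=seed,
        variant=spec.vision_variant,
        naive_mse_per_fold=naive_fold,
        failed_fits=failures,
    )


@dataclass
class ValidationReport:
    """Held-out performance of personalized, global, and naive predictors."""

    variant: str
    personalized_mse: float
    global_mse: float
    naive_mse: float
    naive_probability: float
    m_used: float
    n_test_rows: int
    models: dict[str, CoefficientSet] = field(default_factory=dict, repr=False)
    global_model: CoefficientSet | None = field(default=None, repr=False)

    def __post_init__(self):
        for name in ("personalized_mse", "global_mse", "naive_mse"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 <= self.naive_probability <= 1.0):
            raise ParameterError("naive_probability must lie in [0, 1]")


def holdout_evaluate(train_profiles: Sequence[ParticipantProfile],
                     train_outcomes: Sequence[SubtaskOutcome],
                     test_profiles: Sequence[ParticipantProfile],
                     test_outcomes: Sequence[SubtaskOutcome],
                     spec: ModelSpec,
                     m: float,
                     **fit_kwargs) -> ValidationReport:
    """Held-out validation at matching proportion m.

    Each test participant is matched against *all* training participants and
    receives a personalized fit; the global comparator is the single m = 1.0
    fit; the naive constant is computed from training rows only and applied to
    the test rows.
    """
    train_ids = {p.participant_id for p in train_profiles}
    test_ids = {p.participant_id for p in test_profiles}
    overlap = train_ids & test_ids
    if overlap:
        raise DataError(f"training and test cohorts overlap: {sorted(overlap)[:5]}")
    if not (0.0 < m <= 1.0):
        raise ParameterError(f"matching proportion m must lie in (0, 1], got {m}")
    if not test_outcomes:
        raise DataError("test cohort has no outcome rows")

    scaling = ScalingSpec.fit(train_profiles, spec.vision_variant,
                              spec.include_mped_routine)
    cand_ids, cand_mat = encode_cohort(train_profiles, spec.vision_variant, scaling)
    lookup = {p.participant_id: p for p in train_profiles}

    global_design = build_design(list(train_outcomes), lookup, spec, scaling)
    global_fit = fit_design(global_design, spec, **fit_kwargs)
    global_fit.trained_on = tuple(sorted(train_ids))
    global_fit.m_used = 1.0

    naive_p = naive_baseline_probability([o.n_success for o in train_outcomes],
                                         [o.n_present for o in train_outcomes])

    by_pid: dict[str, list[SubtaskOutcome]] = {}
    for o in test_outcomes:
        if o.participant_id not in test_ids:
            raise DataError(f"test outcome for unknown participant {o.participant_id!r}")
        by_pid.setdefault(o.participant_id, []).append(o)

    pers_errors: list[float] = []
    glob_errors: list[float] = []
    naive_errors: list[float] = []
    models: dict[str, CoefficientSet] = {}
    fit_cache: dict[frozenset, CoefficientSet] = {}

    for target in test_profiles:
        rows = by_pid.get(target.participant_id, [])
        if not rows:
            continue
        tvec = scaling.transform_profiles([target])[0]
        order = rank_candidates(tvec, cand_mat, cand_ids)
        matched = order[:matched_subset_size(m, len(order))]
        key = frozenset(matched)
        if key in fit_cache:
            coeffs = fit_cache[key]
        else:
            coeffs = _fit_matched(matched, train_outcomes, lookup, spec,
                                  scaling, fit_kwargs)
            fit_cache[key] = coeffs
        coeffs = CoefficientSet(**{**coeffs.__dict__})  # shallow copy per target
        coeffs.trained_on = tuple(matched)
        coeffs.m_used = float(m)
        models[target.participant_id] = coeffs
        cov = participant_covariates(target, spec, scaling)
        for o in rows:
            p_pers = predict_from_covariates(coeffs, cov, o.subtask_code, spec)
            p_glob = predict_from_covariates(global_fit, cov, o.subtask_code, spec)
            pers_errors.append(subtask_squared_error(p_pers, o.n_present, o.n_success))
            glob_errors.append(subtask_squared_error(p_glob, o.n_present, o.n_success))
            naive_errors.append(subtask_squared_error(naive_p, o.n_present, o.n_success))

    if not pers_errors:
        raise DataError("no test rows were scored")

    return ValidationReport(
        variant=spec.vision_variant,
        personalized_mse=float(np.mean(pers_errors)),
        global_mse=float(np.mean(glob_errors)),
        naive_mse=float(np.mean(naive_errors)),
        naive_probability=naive_p,
        m_used=float(m),
        n_test_rows=len(pers_errors),
        models=models,
        global_model=global_fit,
    )
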