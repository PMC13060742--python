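"""Per-participant weighted binomial logistic GLMs.

Each personalized model regresses the proportion of subtask success on the
participant's demographic and barrier-score predictors plus one-hot subtask
indicators, with the binomial denominator (times the subtask was present)
entering as the row weight. Fitting is iteratively reweighted least squares
(IRLS, i.e. Newton on the binomial log-likelihood), with an automatic small
ridge penalty on the slopes — never the intercept — as a fallback when the
unpenalized fit separates or fails to converge. Continuous predictors are
standardized with the same :class:`~matppm.similarity.ScalingSpec` used for
cosine matching, so coefficients are comparable across personalized fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import DataError, FitError, MissingDataError, ParameterError, SchemaError
from .similarity import (
    ScalingSpec,
    encode_cohort,
    encode_features,
    feature_fields,
    rank_candidates,
    matched_subset_size,
)
from .study_data import SUBTASK_CODES, ParticipantProfile, SubtaskOutcome

log = logging.getLogger(__name__)

#: Coefficients larger than this on the standardized scale are treated as
#: evidence of separation during IRLS.
_SEPARATION_BOUND = 50.0
_ETA_CLIP = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors enter the GLM and how subtask indicators are coded.

    ``include_age=False`` reproduces the literal predictor set that starts at
    sex; age is included by default. Exactly one vision score enters, chosen by
    ``vision_variant``.
    """

    vision_variant: str = "smat"
    include_age: bool = True
    include_mped_routine: bool = False
    subtask_reference: str | None = None
    taxonomy: tuple[str, ...] = SUBTASK_CODES

    def __post_init__(self):
        if self.subtask_reference is not None and self.subtask_reference not in self.taxonomy:
            raise ParameterError(
                f"subtask reference {self.subtask_reference!r} not in taxonomy")

    @property
    def predictor_fields(self) -> tuple[str, ...]:
        names = feature_fields(self.vision_variant, self.include_mped_routine)
        if not self.include_age:
            names = tuple(n for n in names if n != "age")
        return names

    @property
    def continuous_fields(self) -> tuple[str, ...]:
        return tuple(n for n in self.predictor_fields
                     if n not in ("sex", "hearing_impairment"))


def subtask_column(code: str) -> str:
    return f"subtask[{code}]"


@dataclass
class CoefficientSet:
    """Fitted coefficients of one personalized (or global) GLM.

    ``columns`` always starts with ``"intercept"``; subtask indicator columns
    are named ``subtask[CODE]`` and the reference level carries no coefficient.
    """

    columns: tuple[str, ...]
    values: np.ndarray
    converged: bool
    iterations: int
    penalty_used: float
    log_likelihood: float
    reference_level: str | None = None
    vision_variant: str | None = None
    trained_on: tuple[str, ...] = ()
    m_used: float | None = None
    dropped_columns: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.columns) != len(self.values):
            raise ParameterError("one coefficient per design column required")
        if not self.converged and self.penalty_used <= 0.0:
            raise ParameterError(
                "non-converged fits must record a positive fallback penalty")

    @property
    def intercept(self) -> float:
        return float(self.values[self.columns.index("intercept")])

    @property
    def slopes(self) -> dict[str, float]:
        return {c: float(v) for c, v in zip(self.columns, self.values) if c != "intercept"}

    def coef(self, column: str) -> float:
        return float(self.values[self.columns.index(column)])

    @property
    def subtask_coefficients(self) -> dict[str, float]:
        out = {}
        for c, v in zip(self.columns, self.values):
            if c.startswith("subtask["):
                out[c[len("subtask["):-1]] = float(v)
        return out

    # -- plain-text serialization (one model per file, fully auditable) ------

    def to_text(self) -> str:
        lines = [
            "schema=matppm-coefficients/1",
            f"vision_variant={self.vision_variant or ''}",
            f"reference_level={self.reference_level or ''}",
            f"m_used={'' if self.m_used is None else repr(float(self.m_used))}",
            f"penalty_used={float(self.penalty_used)!r}",
            f"converged={str(self.converged).lower()}",
            f"iterations={self.iterations}",
            f"log_likelihood={float(self.log_likelihood)!r}",
            f"trained_on={','.join(self.trained_on)}",
            f"dropped_columns={','.join(self.dropped_columns)}",
        ]
        lines += [f"coef[{c}]={float(v)!r}" for c, v in zip(self.columns, self.values)]
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")

    @classmethod
    def from_text(cls, text: str) -> "CoefficientSet":
        kv: dict[str, str] = {}
        cols: list[str] = []
        vals: list[float] = []
        for line in text.strip().splitlines():
            key, _, value = line.partition("=")
            if key.startswith("coef["):
                cols.append(key[len("coef["):-1])
                vals.append(float(value))
            else:
                kv[key] = value
        if kv.get("schema") != "matppm-coefficients/1":
            raise SchemaError(f"unrecognized coefficient file schema {kv.get('schema')!r}")
        return cls(
            columns=tuple(cols),
            values=np.array(vals),
            converged=kv["converged"] == "true",
            iterations=int(kv["iterations"]),
            penalty_used=float(kv["penalty_used"]),
            log_likelihood=float(kv["log_likelihood"]),
            reference_level=kv["reference_level"] or None,
            vision_variant=kv["vision_variant"] or None,
            trained_on=tuple(t for t in kv["trained_on"].split(",") if t),
            m_used=float(kv["m_used"]) if kv["m_used"] else None,
            dropped_columns=tuple(t for t in kv["dropped_columns"].split(",") if t),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CoefficientSet":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))


@dataclass
class Design:
    """Design matrix plus binomial response for one fit."""

    X: np.ndarray
    columns: tuple[str, ...]
    successes: np.ndarray
    trials: np.ndarray                 # also the row weights ("task count weights")
    row_participants: tuple[str, ...]
    reference_level: str
    dropped_columns: tuple[str, ...] = ()

    @property
    def weights(self) -> np.ndarray:
        return self.trials


def participant_covariates(profile: ParticipantProfile, spec: ModelSpec,
                           scaling: ScalingSpec) -> dict[str, float]:
    """Non-subtask covariate values for one participant, as used in the design.

    Continuous predictors are standardized; sex (0=female, 1=male) and the
    hearing-impairment fraction enter raw.
    """
    if scaling.vision_variant != spec.vision_variant:
        raise ParameterError("scaling and model spec use different vision variants")
    cov: dict[str, float] = {}
    continuous = set(spec.continuous_fields)
    for name in spec.predictor_fields:
        if name == "sex":
            cov[name] = float(profile.sex_code)
        elif name == "hearing_impairment":
            cov[name] = float(profile.hearing_impairment)
        else:
            raw = getattr(profile, name, None)
            if raw is None:
                raise MissingDataError(f"profile field missing: {name}")
            if name in continuous:
                if name in scaling.dropped:
                    # constant on the training cohort; carries no information
                    cov[name] = 0.0
                else:
                    cov[name] = scaling.standardize(name, float(raw))
            else:
                cov[name] = float(raw)
    return cov


def build_design(outcomes: Sequence[SubtaskOutcome],
                 profiles: Mapping[str, ParticipantProfile],
                 spec: ModelSpec,
                 scaling: ScalingSpec) -> Design:
    """Assemble the weighted binomial design for a set of outcome rows.

    One row per outcome; columns are intercept, predictors, then one-hot
    subtask indicators excluding the reference level (the lexicographically
    first code present unless the spec pins one). All-constant columns other
    than the intercept are dropped with a log entry.
    """
    if not outcomes:
        raise DataError("cannot build a design from zero outcome rows")
    present = sorted({o.subtask_code for o in outcomes})
    unknown = [c for c in present if c not in spec.taxonomy]
    if unknown:
        raise SchemaError(f"subtask codes not in taxonomy: {unknown}")
    reference = spec.subtask_reference
    if reference is None or reference not in present:
        if spec.subtask_reference is not None:
            log.debug("pinned reference %s absent from data; using first present",
                      spec.subtask_reference)
        reference = present[0]
    dummy_codes = [c for c in present if c != reference]

    cov_cache: dict[str, dict[str, float]] = {}
    for pid in {o.participant_id for o in outcomes}:
        if pid not in profiles:
            raise DataError(f"no profile for participant {pid!r}")
        cov_cache[pid] = participant_covariates(profiles[pid], spec, scaling)

    pred_names = list(spec.predictor_fields)
    columns = ["intercept"] + pred_names + [subtask_column(c) for c in dummy_codes]
    code_index = {c: len(pred_names) + 1 + i for i, c in enumerate(dummy_codes)}

    X = np.zeros((len(outcomes), len(columns)))
    successes = np.empty(len(outcomes), dtype=float)
    trials = np.empty(len(outcomes), dtype=float)
    row_pids = []
    for r, o in enumerate(outcomes):
        cov = cov_cache[o.participant_id]
        X[r, 0] = 1.0
        for j, name in enumerate(pred_names, start=1):
            X[r, j] = cov[name]
        if o.subtask_code != reference:
            X[r, code_index[o.subtask_code]] = 1.0
        successes[r] = o.n_success
        trials[r] = o.n_present
        row_pids.append(o.participant_id)

    # drop non-intercept columns with zero variance (constant in this subset)
    keep = [0] + [j for j in range(1, len(columns))
                  if np.ptp(X[:, j]) > 0.0]
    dropped = tuple(columns[j] for j in range(len(columns)) if j not in keep)
    if dropped:
        log.debug("build_design: dropping constant columns %s", dropped)
        X = X[:, keep]
        columns = [columns[j] for j in keep]

    return Design(
        X=X,
        columns=tuple(columns),
        successes=successes,
        trials=trials,
        row_participants=tuple(row_pids),
        reference_level=reference,
        dropped_columns=dropped,
    )


def binomial_log_likelihood(beta: np.ndarray, X: np.ndarray, successes: np.ndarray,
                            trials: np.ndarray) -> float:
    """Binomial log-likelihood sum s*log(p) + (n-s)*log(1-p), logit p = X beta."""
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    # log(p) = -log1p(exp(-eta)); log(1-p) = -log1p(exp(eta))
    return float(np.sum(successes * -np.log1p(np.exp(-eta))
                        + (trials - successes) * -np.log1p(np.exp(eta))))


def _penalized_ll(beta, X, s, n, ridge, slope_mask):
    pen = 0.5 * ridge * float(np.sum((beta * slope_mask) ** 2))
    return binomial_log_likelihood(beta, X, s, n) - pen


def _irls(X, s, n, ridge, tol, max_iter, slope_mask):
    beta = np.zeros(X.shape[1])
    ll = _penalized_ll(beta, X, s, n, ridge, slope_mask)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = n * p * (1.0 - p)
        grad = X.T @ (s - n * p) - ridge * (beta * slope_mask)
        H = (X * w[:, None]).T @ X + ridge * np.diag(slope_mask)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False, it, ll
        # step-halving guard: never accept a step that lowers the objective
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            cand_ll = _penalized_ll(cand, X, s, n, ridge, slope_mask)
            if cand_ll >= ll - 1e-12:
                break
            t *= 0.5
        else:
            return beta, False, it, ll
        beta, ll = cand, cand_ll
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            return beta, False, it, ll
        if np.max(np.abs(t * step)) < tol:
            return beta, True, it, ll
    return beta, False, max_iter, ll


def fit_binomial_glm(X: np.ndarray,
                     successes: np.ndarray,
                     trials: np.ndarray,
                     columns: Sequence[str] | None = None,
                     ridge: float = 0.0,
                     tol: float = 1e-8,
                     max_iter: int = 100,
                     fallback_ridge: float = 1e-4,
                     allow_fallback: bool = True) -> CoefficientSet:
    """Maximum-likelihood weighted binomial logistic fit via IRLS.

    Maximizes ``sum s_i log p_i + (n_i - s_i) log(1 - p_i)`` with
    ``logit p_i = x_i' beta``, minus ``(ridge/2)*||beta_slopes||^2`` when a
    ridge is requested. If the unpenalized fit separates or stalls, the model
    is refit with ``fallback_ridge`` on the slopes (never the intercept) and
    the penalty is recorded in the result.
    """
    if ridge < 0.0:
        raise ParameterError("ridge must be non-negative")
    X = np.asarray(X, dtype=float)
    s = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if np.any(s < 0) or np.any(s > n) or np.any(n < 1):
        raise ParameterError("responses must satisfy 0 <= successes <= trials, trials >= 1")
    if columns is None:
        columns = tuple(["intercept"] + [f"x{j}" for j in range(1, X.shape[1])])
    columns = tuple(columns)
    slope_mask = np.array([0.0 if c == "intercept" else 1.0 for c in columns])

    beta, converged, iters, ll = _irls(X, s, n, ridge, tol, max_iter, slope_mask)
    penalty = ridge
    if not converged:
        if not allow_fallback:
            raise FitError(
                "IRLS did not converge and fallback is disabled",
                diagnostics={"iterations": iters, "max_abs_beta": float(np.max(np.abs(beta)))},
            )
        penalty = max(ridge, fallback_ridge)
        log.debug("IRLS fallback: refitting with ridge %g on slopes", penalty)
        beta, converged, iters, ll = _irls(X, s, n, penalty, tol, max_iter, slope_mask)

    return CoefficientSet(
        columns=columns,
        values=beta,
        converged=converged,
        iterations=iters,
        penalty_used=penalty,
        log_likelihood=binomial_log_likelihood(beta, X, s, n),
    )


def fit_design(design: Design, spec: ModelSpec, **fit_kwargs) -> CoefficientSet:
    """Fit a :class:`Design`, carrying its metadata onto the coefficients."""
    coeffs = fit_binomial_glm(design.X, design.successes, design.trials,
                              columns=design.columns, **fit_kwargs)
    coeffs.reference_level = design.reference_level
    coeffs.vision_variant = spec.vision_variant
    coeffs.dropped_columns = design.dropped_columns
    return coeffs


def linear_row(coeffs: CoefficientSet, covariates: Mapping[str, float],
               subtask_code: str) -> np.ndarray:
    """Assemble the design row for (covariates, subtask) in ``coeffs`` column order."""
    row = np.empty(len(coeffs.columns))
    target_col = subtask_column(subtask_code)
    for j, c in enumerate(coeffs.columns):
        if c == "intercept":
            row[j] = 1.0
        elif c.startswith("subtask["):
            row[j] = 1.0 if c == target_col else 0.0
        else:
            if c not in covariates:
                raise MissingDataError(f"covariate missing for prediction: {c}")
            row[j] = covariates[c]
    return row


def predict_from_covariates(coeffs: CoefficientSet, covariates: Mapping[str, float],
                            subtask_code: str, spec: ModelSpec) -> float:
    if subtask_code not in spec.taxonomy:
        raise SchemaError(f"subtask code {subtask_code!r} not in taxonomy")
    if (subtask_code != coeffs.reference_level
            and subtask_column(subtask_code) not in coeffs.columns):
        log.warning("subtask %s unseen in training; predicting at reference level %s",
                    subtask_code, coeffs.reference_level)
    eta = float(np.dot(linear_row(coeffs, covariates, subtask_code), coeffs.values))
    return float(expit(eta))


def predict_probability(coeffs: CoefficientSet, profile: ParticipantProfile,
                        subtask_code: str, spec: ModelSpec,
                        scaling: ScalingSpec) -> float:
    """Predicted probability of subtask success, strictly inside (0, 1).

    The linear predictor is assembled exactly as :func:`build_design` assembles
    rows; a subtask code unseen at training time falls back to the reference
    level with a logged warning.
    """
    cov = participant_covariates(profile, spec, scaling)
    return predict_from_covariates(coeffs, cov, subtask_code, spec)


def fit_personalized(target: ParticipantProfile,
                     training_profiles: Sequence[ParticipantProfile],
                     training_outcomes: Sequence[SubtaskOutcome],
                     m: float,
                     spec: ModelSpec,
                     scaling: ScalingSpec | None = None,
                     **fit_kwargs) -> CoefficientSet:
    """Fit the personalized GLM for one target participant.

    Encodes profiles, selects the top m*100% most similar training
    participants (the target itself is always excluded), builds the design on
    the matched participants' outcomes only, and fits. ``m = 1.0`` uses every
    training participant and therefore yields the global (nonpersonalized)
    model, identical for every target.
    """
    candidates = [p for p in training_profiles
                  if p.participant_id != target.participant_id]
    if not candidates:
        raise DataError("no training candidates after excluding the target")
    if scaling is None:
        scaling = ScalingSpec.fit(candidates, spec.vision_variant,
                                  spec.include_mped_routine)
    cand_ids, cand_mat = encode_cohort(candidates, spec.vision_variant, scaling)
    tvec = encode_features(target, spec.vision_variant, scaling)
    count = matched_subset_size(m, len(candidates))
    matched = rank_candidates(tvec.values, cand_mat, cand_ids)[:count]
    matched_set = set(matched)
    # canonical (input) row order keeps fits independent of similarity ranking
    subset = [o for o in training_outcomes if o.participant_id in matched_set]
    if not subset:
        raise DataError(
            f"matched subset for {target.participant_id!r} has no outcome rows")
    lookup = {p.participant_id: p for p in candidates}
    design = build_design(subset, lookup, spec, scaling)
    coeffs = fit_design(design, spec, **fit_kwargs)
    coeffs.trained_on = tuple(matched)
    coeffs.m_used = float(m)
    return coeffs
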