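"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study's marginals — a truncated-normal age
distribution, the usability-sample barrier prevalences, whisper-test ear
results, a sparse device/subtask exposure structure (1-7 devices per
participant from a pool of 13, each device exercising 4-10 of the 32 subtask
codes, 1-3 attempts per subtask) — and draws subtask successes from a
binomial logistic process whose intercept is auto-calibrated so the pooled
expected success proportion hits a target (default 0.87, the observed
training-data mean), producing the characteristic left-skewed outcome.

Optional latent subgroups with different slope vectors create a regime where
personalization genuinely helps; with a single subgroup the population is a
homogeneous logistic model and personalization must show no benefit. The
ground truth (coefficients, subgroup assignment) is returned as a
:class:`TruthSet` for parameter-recovery testing.

Score distributions are a modeling choice, not an observed fact: only band
counts are known for the instrument scores, so continuous values are drawn
uniformly within each band, with non-barrier bands kept strictly above the
barrier cut so that derived flags reproduce the configured prevalences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigError, DataError
from .personalized_model import CoefficientSet, ModelSpec, participant_covariates, subtask_column
from .similarity import ScalingSpec
from .study_data import SUBTASK_CODES, ParticipantProfile, SubtaskOutcome

log = logging.getLogger(__name__)

#: Usability-sample (n=96) marginals: barrier prevalences by domain.
USABILITY_PREVALENCES: dict[str, float] = {
    "cognitive": 21 / 96,
    "physical": 37 / 96,
    "vision_smat": 23 / 96,
    "vision_dltv": 37 / 96,
    "hearing_both": 55 / 96,
    "motivation": 34 / 96,
    "environment": 34 / 96,
}

#: Validation-sample (n=21) marginals.
VALIDATION_PREVALENCES: dict[str, float] = {
    "cognitive": 6 / 21,
    "physical": 6 / 21,
    "vision_smat": 3 / 21,
    "vision_dltv": 10 / 21,
    "hearing_both": 12 / 21,
    "motivation": 3 / 21,
    "environment": 5 / 21,
}

#: Within-barrier band splits (moderate vs low) taken from the reported counts.
_COG_MODERATE_SHARE = 7 / 21
_PHY_MODLOW_SHARE = 11 / 37
_VIS_MODLOW_SHARE = 4 / 23


@dataclass
class PopulationConfig:
    """Marginals and exposure structure for one simulated cohort."""

    n_participants: int
    age_mean: float = 75.11
    age_sd: float = 7.70
    age_range: tuple[int, int] = (61, 95)
    sex_split: float = 0.625            # proportion female
    barrier_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(USABILITY_PREVALENCES))
    one_ear_fail_rate: float = 0.15
    medication_use_rate: float = 0.896
    n_devices: int = 13
    devices_per_participant: tuple[int, int] = (1, 7)
    codes_per_device: tuple[int, int] = (4, 10)
    attempts_per_subtask: tuple[int, int] = (1, 3)
    subtask_taxonomy: tuple[str, ...] = SUBTASK_CODES
    seed: int = 0
    cohort: str = "training"
    id_prefix: str = "P"
    id_start: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        for key, p in self.barrier_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"prevalence {key}={p} outside [0, 1]")
        needed = set(USABILITY_PREVALENCES)
        if set(self.barrier_prevalences) != needed:
            raise ConfigError(f"barrier_prevalences must have keys {sorted(needed)}")
        if self.barrier_prevalences["hearing_both"] + self.one_ear_fail_rate > 1.0:
            raise ConfigError("hearing_both prevalence + one-ear rate exceeds 1")
        for name in ("devices_per_participant", "codes_per_device", "attempts_per_subtask"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} range ({lo}, {hi}) is empty or invalid")
        if self.devices_per_participant[1] > self.n_devices:
            raise ConfigError("cannot test more devices than exist")
        if self.codes_per_device[1] > len(self.subtask_taxonomy):
            raise ConfigError("codes_per_device exceeds taxonomy size")
        if not (self.age_range[0] < self.age_range[1]):
            raise ConfigError("age_range is empty")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be positive")


def _banded_scores(rng, n, prevalence, moderate_share, moderate_band, low_band):
    """SMAT-style scores: barrier bands below the cut, non-barrier above 90."""
    barrier = rng.random(n) < prevalence
    moderate = rng.random(n) < moderate_share
    scores = rng.uniform(90.0, 100.0, n)
    lo, hi = moderate_band
    scores = np.where(barrier & moderate, rng.uniform(lo, hi, n), scores)
    lo, hi = low_band
    scores = np.where(barrier & ~moderate, rng.uniform(lo, hi, n), scores)
    return np.round(scores, 1)


def simulate_profiles(config: PopulationConfig) -> list[ParticipantProfile]:
    """Draw a cohort of participant profiles matching the configured marginals.

    Deterministic under the config seed; barrier flags derived from the
    generated scores reproduce the configured prevalences in expectation.
    """
    n = config.n_participants
    rng = np.random.default_rng([config.seed, config.id_start, 0])
    prev = config.barrier_prevalences

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                         size=n, random_state=rng)
    ages = np.clip(np.rint(ages), lo, hi).astype(int)

    female = rng.random(n) < config.sex_split

    cog = _banded_scores(rng, n, prev["cognitive"], _COG_MODERATE_SHARE,
                         (70.0, 79.0), (50.0, 69.0))
    phy = _banded_scores(rng, n, prev["physical"], _PHY_MODLOW_SHARE,
                         (76.0, 84.0), (55.0, 75.0))
    vis = _banded_scores(rng, n, prev["vision_smat"], _VIS_MODLOW_SHARE,
                         (76.0, 84.0), (55.0, 75.0))

    dltv_barrier = rng.random(n) < prev["vision_dltv"]
    dltv = np.round(np.where(dltv_barrier,
                             rng.uniform(50.0, 78.0, n),
                             rng.uniform(79.0, 110.0, n)), 1)

    seams_barrier = rng.random(n) < prev["motivation"]
    seams = np.round(np.where(seams_barrier,
                              rng.uniform(20.0, 39.0, n),
                              rng.uniform(40.0, 52.0, n)), 1)

    env_barrier = rng.random(n) < prev["environment"]
    busy = np.round(np.where(env_barrier,
                             rng.uniform(15.0, 25.0, n),
                             rng.uniform(5.0, 14.0, n)), 1)
    routine = np.round(np.where(env_barrier,
                                rng.uniform(10.0, 28.0, n),
                                rng.uniform(16.0, 30.0, n)), 1)

    u = rng.random(n)
    hearing = np.where(u < prev["hearing_both"], 1.0,
                       np.where(u < prev["hearing_both"] + config.one_ear_fail_rate,
                                0.5, 0.0))

    uses_meds = rng.random(n) < config.medication_use_rate
    med_count = np.where(uses_meds, 1 + rng.poisson(2.5, n), 0)
    hist_count = rng.poisson(2.6, n)

    profiles = []
    for i in range(n):
        profiles.append(ParticipantProfile(
            participant_id=f"{config.id_prefix}{config.id_start + i + 1:04d}",
            age=int(ages[i]),
            sex="female" if female[i] else "male",
            medication_count=int(med_count[i]),
            medical_history_count=int(hist_count[i]),
            cognitive_score=float(cog[i]),
            physical_score=float(phy[i]),
            smat_vision_score=float(vis[i]),
            dltv_summary_vision_score=float(dltv[i]),
            seams_score=float(seams[i]),
            mped_busyness_score=float(busy[i]),
            mped_routine_score=float(routine[i]),
            hearing_impairment=float(hearing[i]),
            cohort=config.cohort,
        ))
    return profiles


@dataclass
class TruthSet:
    """Ground-truth data-generating model for recovery and ordering tests."""

    coefficient_sets: list[CoefficientSet]       # one per latent subgroup
    subgroup_of: dict[str, int]
    mixing_proportion: float
    scaling: ScalingSpec
    reference_level: str
    target_mean_success: float | None = 0.87
    calibrated: bool = False

    @property
    def n_subgroups(self) -> int:
        return len(self.coefficient_sets)

    def to_json_text(self) -> str:
        payload = {
            "schema": "matppm-truth/1",
            "mixing_proportion": self.mixing_proportion,
            "target_mean_success": self.target_mean_success,
            "calibrated": self.calibrated,
            "reference_level": self.reference_level,
            "subgroup_of": self.subgroup_of,
            "coefficient_sets": [
                {"columns": list(c.columns), "values": [float(v) for v in c.values]}
                for c in self.coefficient_sets
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json_text(), encoding="utf-8")


def make_truth(profiles: Sequence[ParticipantProfile],
               subgroup_slopes: Sequence[Mapping[str, float]],
               mixing_proportion: float = 0.0,
               seed: int = 0,
               subtask_effect_sd: float = 0.4,
               target_mean_success: float | None = 0.87,
               intercept: float = 0.0,
               assignment: Mapping[str, int] | None = None,
               assignment_noise: float = 0.7,
               spec: ModelSpec | None = None) -> TruthSet:
    """Build the generating coefficients and subgroup assignment for a cohort.

    Slope dictionaries are keyed by predictor field name on the standardized
    design scale (unlisted predictors get slope 0); subtask effects are drawn
    N(0, ``subtask_effect_sd``) once and shared across subgroups. Without an
    explicit assignment, subgroup membership is correlated with the
    functional-score composite (more impaired participants land in the last
    subgroup), which is what lets similarity matching recover subgroups.
    """
    if spec is None:
        spec = ModelSpec()
    rng = np.random.default_rng([seed, 3])
    scaling = ScalingSpec.fit(profiles, spec.vision_variant, spec.include_mped_routine)
    reference = spec.taxonomy[0]
    other_codes = [c for c in spec.taxonomy if c != reference]
    offsets = rng.normal(0.0, subtask_effect_sd, len(other_codes))

    pred = list(spec.predictor_fields)
    columns = tuple(["intercept"] + pred + [subtask_column(c) for c in other_codes])
    sets = []
    for slopes in subgroup_slopes:
        unknown = set(slopes) - set(pred)
        if unknown:
            raise ConfigError(f"slope keys not among predictors: {sorted(unknown)}")
        values = np.concatenate([
            [intercept],
            [float(slopes.get(name, 0.0)) for name in pred],
            offsets,
        ])
        sets.append(CoefficientSet(
            columns=columns, values=values, converged=True, iterations=0,
            penalty_used=0.0, log_likelihood=float("nan"),
            reference_level=reference, vision_variant=spec.vision_variant,
        ))

    ids = [p.participant_id for p in profiles]
    if assignment is not None:
        subgroup_of = {pid: int(assignment[pid]) for pid in ids}
    elif len(sets) == 1:
        subgroup_of = {pid: 0 for pid in ids}
    else:
        if len(sets) != 2:
            raise ConfigError("automatic assignment supports exactly 2 subgroups")
        from .similarity import VISION_FIELD

        comp_fields = ["cognitive_score", "physical_score",
                       VISION_FIELD[spec.vision_variant], "seams_score"]
        comp_fields = [f for f in comp_fields if f in scaling.feature_names]
        if not comp_fields:
            raise ConfigError("functional-score composite is constant; cannot assign subgroups")
        composite = np.array([
            sum(scaling.standardize(f, getattr(p, f)) for f in comp_fields)
            for p in profiles
        ]) / len(comp_fields)
        latent = composite + assignment_noise * rng.normal(size=len(profiles))
        cut = np.quantile(latent, mixing_proportion)
        subgroup_of = {pid: int(latent[i] <= cut) for i, pid in enumerate(ids)}

    return TruthSet(
        coefficient_sets=sets,
        subgroup_of=subgroup_of,
        mixing_proportion=mixing_proportion,
        scaling=scaling,
        reference_level=reference,
        target_mean_success=target_mean_success,
    )


def simulate_outcomes(profiles: Sequence[ParticipantProfile],
                      truth: TruthSet,
                      config: PopulationConfig,
                      spec: ModelSpec | None = None) -> list[SubtaskOutcome]:
    """Draw device exposures and binomial subtask outcomes under the truth.

    Each synthetic device carries a fixed random subset of subtask codes; each
    participant tests a random handful of devices. If the truth declares a
    target mean success and has not been calibrated yet, a common intercept
    shift is solved (root-finding) so the exposure-weighted expected success
    proportion equals the target, and the truth's intercepts are updated in
    place.
    """
    if spec is None:
        spec = ModelSpec()
    for p in profiles:
        if p.participant_id not in truth.subgroup_of:
            raise DataError(f"participant {p.participant_id!r} has no subgroup assignment")

    rng_dev = np.random.default_rng([config.seed, 2])
    taxonomy = list(config.subtask_taxonomy)
    lo, hi = config.codes_per_device
    device_codes = []
    for _ in range(config.n_devices):
        size = int(rng_dev.integers(lo, hi + 1))
        codes = sorted(rng_dev.choice(len(taxonomy), size=size, replace=False))
        device_codes.append([taxonomy[c] for c in codes])

    rng = np.random.default_rng([config.seed, config.id_start, 1])
    d_lo, d_hi = config.devices_per_participant
    a_lo, a_hi = config.attempts_per_subtask

    # per-participant linear-predictor base (everything except subtask effect)
    code_pos = {c: i for i, c in enumerate(taxonomy)}
    offset_by_code = np.zeros(len(taxonomy))
    ref = truth.reference_level
    for c in taxonomy:
        if c != ref:
            col = subtask_column(c)
            cs = truth.coefficient_sets[0]
            if col in cs.columns:
                offset_by_code[code_pos[c]] = cs.coef(col)

    eta_base = np.empty(len(profiles))
    for i, p in enumerate(profiles):
        cs = truth.coefficient_sets[truth.subgroup_of[p.participant_id]]
        cov = participant_covariates(p, spec, truth.scaling)
        eta = cs.intercept
        for name in spec.predictor_fields:
            eta += cs.coef(name) * cov[name]
        eta_base[i] = eta

    row_part: list[int] = []
    row_code: list[int] = []
    row_dev: list[int] = []
    for i in range(len(profiles)):
        ndev = int(rng.integers(d_lo, d_hi + 1))
        devices = rng.choice(config.n_devices, size=ndev, replace=False)
        for d in sorted(devices):
            for code in device_codes[d]:
                row_part.append(i)
                row_code.append(code_pos[code])
                row_dev.append(d)
    row_part = np.array(row_part)
    row_code = np.array(row_code)
    n_present = rng.integers(a_lo, a_hi + 1, size=len(row_part))

    eta = eta_base[row_part] + offset_by_code[row_code]

    if truth.target_mean_success is not None and not truth.calibrated:
        target = truth.target_mean_success
        total = float(n_present.sum())

        def pooled(delta):
            return float(np.sum(n_present * expit(eta + delta))) / total - target

        delta = brentq(pooled, -20.0, 20.0)
        for cs in truth.coefficient_sets:
            cs.values = cs.values.copy()
            cs.values[0] += delta
        truth.calibrated = True
        eta = eta + delta
        log.debug("calibrated intercept shift %.4f for target %.2f", delta, target)

    p_success = expit(eta)
    successes = rng.binomial(n_present, p_success)

    outcomes = []
    for r in range(len(row_part)):
        outcomes.append(SubtaskOutcome(
            participant_id=profiles[row_part[r]].participant_id,
            device_id=f"D{row_dev[r] + 1:02d}",
            subtask_code=taxonomy[row_code[r]],
            n_present=int(n_present[r]),
            n_failed=int(n_present[r] - successes[r]),
        ))
    return outcomes


# ---------------------------------------------------------------------------
# Canned cohorts
# ---------------------------------------------------------------------------

#: Moderate homogeneous effects on the standardized design scale.
DEFAULT_SLOPES: dict[str, float] = {
    "cognitive_score": 0.6,
    "physical_score": 0.4,
    "smat_vision_score": 0.4,
    "seams_score": 0.3,
    "age": -0.3,
    "hearing_impairment": -0.4,
}

#: Effects shared by every subgroup: the learnable common structure that lets
#: covariate-informed models (personalized and global alike) beat the naive
#: constant, as the subtask-level modeling premise requires.
_COMMON_SLOPES: dict[str, float] = {
    "age": -0.4,
    "hearing_impairment": -0.6,
    "medication_count": -0.2,
    "mped_busyness_score": -0.3,
}
_OPPOSED_FIELDS = ("cognitive_score", "physical_score", "smat_vision_score", "seams_score")


def homogeneous_cohort(n_participants: int, seed: int,
                       slopes: Mapping[str, float] | None = None,
                       target_mean_success: float | None = 0.87,
                       **config_overrides):
    """One-subgroup cohort: a plain weighted binomial logistic population."""
    config = PopulationConfig(n_participants=n_participants, seed=seed,
                              **config_overrides)
    profiles = simulate_profiles(config)
    truth = make_truth(profiles, [dict(slopes or DEFAULT_SLOPES)],
                       mixing_proportion=0.0, seed=seed,
                       target_mean_success=target_mean_success)
    outcomes = simulate_outcomes(profiles, truth, config)
    return profiles, outcomes, truth


def two_subgroup_cohort(n_participants: int, separation: float, seed: int,
                        mixing_proportion: float = 0.5,
                        target_mean_success: float | None = 0.87,
                        low_prevalence: float = 0.12,
                        high_prevalence: float = 0.80,
                        subtask_effect_sd: float = 0.8):
    """Two latent subgroups with opposite-sign functional-score slopes.

    Subgroup feature distributions are shifted (low vs high barrier
    prevalences) so that cosine matching can recover subgroup structure;
    ``separation`` scales the opposed slopes (0 reduces to a homogeneous
    cohort with only the common age/hearing effects).
    """
    n1 = int(round(n_participants * mixing_proportion))
    n0 = n_participants - n1
    prev_low = {k: low_prevalence for k in USABILITY_PREVALENCES}
    prev_high = {k: high_prevalence for k in USABILITY_PREVALENCES}
    cfg0 = PopulationConfig(n_participants=n0, seed=seed, id_start=0,
                            barrier_prevalences=prev_low)
    cfg1 = PopulationConfig(n_participants=n1, seed=seed, id_start=n0,
                            barrier_prevalences=prev_high)
    profiles = simulate_profiles(cfg0) + simulate_profiles(cfg1)
    assignment = {p.participant_id: (0 if i < n0 else 1)
                  for i, p in enumerate(profiles)}
    slopes0 = dict(_COMMON_SLOPES)
    slopes1 = dict(_COMMON_SLOPES)
    for name in _OPPOSED_FIELDS:
        slopes0[name] = +separation
        slopes1[name] = -separation
    truth = make_truth(profiles, [slopes0, slopes1],
                       mixing_proportion=mixing_proportion, seed=seed,
                       assignment=assignment,
                       subtask_effect_sd=subtask_effect_sd,
                       target_mean_success=target_mean_success)
    exposure_cfg = PopulationConfig(n_participants=n_participants, seed=seed)
    outcomes = simulate_outcomes(profiles, truth, exposure_cfg)
    return profiles, outcomes, truth


@dataclass
class StudyFixture:
    """A synthetic analogue of the full study: 96 training + 21 validation."""

    train_profiles: list[ParticipantProfile]
    train_outcomes: list[SubtaskOutcome]
    test_profiles: list[ParticipantProfile]
    test_outcomes: list[SubtaskOutcome]
    truth: TruthSet

    @property
    def all_profiles(self) -> list[ParticipantProfile]:
        return self.train_profiles + self.test_profiles

    @property
    def all_outcomes(self) -> list[SubtaskOutcome]:
        return self.train_outcomes + self.test_outcomes


def study_fixture(seed: int = 0,
                  n_train: int = 96,
                  n_test: int = 21,
                  separation: float = 0.6) -> StudyFixture:
    """One call yields a complete, schema-valid study-shaped dataset.

    Training-analog participants follow the usability-sample marginals and
    validation-analog participants the validation-sample marginals; outcomes
    come from a two-subgroup logistic truth (membership correlated with the
    functional-score composite) calibrated to a pooled success proportion
    of 0.87.
    """
    cfg_train = PopulationConfig(n_participants=n_train, seed=seed,
                                 cohort="training", id_start=0)
    cfg_test = PopulationConfig(
        n_participants=n_test, seed=seed, cohort="validation", id_start=n_train,
        age_mean=73.42, age_sd=8.56, age_range=(60, 84), sex_split=7 / 21,
        barrier_prevalences=dict(VALIDATION_PREVALENCES))
    train_profiles = simulate_profiles(cfg_train)
    test_profiles = simulate_profiles(cfg_test)
    combined = train_profiles + test_profiles

    slopes0 = dict(_COMMON_SLOPES)
    slopes1 = dict(_COMMON_SLOPES)
    for name in _OPPOSED_FIELDS:
        slopes0[name] = +separation
        slopes1[name] = -separation
    truth = make_truth(combined, [slopes0, slopes1], mixing_proportion=0.5,
                       seed=seed, target_mean_success=0.87)
    outcomes = simulate_outcomes(combined, truth, cfg_train)
    train_ids = {p.participant_id for p in train_profiles}
    return StudyFixture(
        train_profiles=train_profiles,
        train_outcomes=[o for o in outcomes if o.participant_id in train_ids],
        test_profiles=test_profiles,
        test_outcomes=[o for o in outcomes if o.participant_id not in train_ids],
        truth=truth,
    )
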