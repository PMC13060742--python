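"""Participant and subtask-outcome data model.

This module defines the two study tables — participant profiles (demographics,
medication burden, and functional-barrier instrument scores) and per-device
subtask outcomes (attempt / failure counts) — together with:

* the outcome measure, the proportion of subtask success
  ``(n_present - n_failed) / n_present``;
* whisper-test hearing coding (both ears fail -> 1.0, one ear -> 0.5,
  none -> 0.0);
* barrier-flag derivation from the instrument cutoffs (DLTV total < 79,
  SEAMS total < 40, MPED busyness >= 15 or routine < 16, SMAT score bands);
* dataset validation and the delimited-text (CSV) schemas.

Instrument scores are consumed as totals/subscales only; scoring the
instruments themselves is out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    InconsistentCountsError,
    InvalidExposureError,
    MissingDataError,
    SchemaError,
)

log = logging.getLogger(__name__)

#: The 32-code subtask taxonomy (device-feature level actions, e.g. A2 =
#: "insert the battery correctly", D4 = "fill medication in the compartment").
SUBTASK_CODES: tuple[str, ...] = (
    "A1", "A2", "A3", "A4", "A5", "A6",
    "B1", "B2", "B3", "B4",
    "C1", "C2",
    "D1", "D2", "D3", "D4", "D5", "D6",
    "G1", "G2", "G3",
    "H1",
    "I1", "I2", "I3",
    "M1",
    "P1",
    "R1", "R2",
    "T1", "T2",
    "U1",
)

SEX_CODES: Mapping[str, int] = {"female": 0, "male": 1}
COHORTS = ("training", "validation")

# Barrier cutoffs. SMAT bands put "high" at >= 90 and the moderate/low bands at
# <= 84; a barrier is a low or moderate-to-low score, so the cut is <= 84.
# Scores in the 85-89 gap map to the nearest higher band (non-barrier).
SMAT_BARRIER_CUT = 84.0       # barrier present when score <= this
DLTV_BARRIER_CUT = 79.0       # barrier present when total < this
SEAMS_BARRIER_CUT = 40.0      # barrier present when total < this
MPED_BUSYNESS_CUT = 15.0      # barrier present when busyness >= this
MPED_ROUTINE_CUT = 16.0       # barrier present when routine < this

PARTICIPANT_SCHEMA_VERSION = "1"
OUTCOME_SCHEMA_VERSION = "1"

PARTICIPANT_COLUMNS: tuple[str, ...] = (
    "participant_id", "age", "sex", "medication_count", "medical_history_count",
    "cognitive_score", "physical_score", "smat_vision_score",
    "dltv_summary_vision_score", "seams_score", "mped_busyness_score",
    "mped_routine_score", "hearing_impairment", "left_ear_pass",
    "right_ear_pass", "cohort",
)
OUTCOME_COLUMNS: tuple[str, ...] = (
    "participant_id", "device_id", "subtask_code", "n_present", "n_failed",
)


def proportion_subtask_success(n_present: int, n_failed: int) -> float:
    """Proportion of subtask success: (present - failed) / present.

    Parameters
    ----------
    n_present
        Number of times the subtask was present in device use. Must be >= 1.
    n_failed
        Number of times the participant failed the subtask.

    Returns
    -------
    float in [0, 1].
    """
    if n_present is None or n_failed is None:
        raise MissingDataError("n_present and n_failed must both be observed")
    if n_present < 1:
        raise InvalidExposureError(
            f"subtask exposure requires n_present >= 1, got {n_present}"
        )
    if n_failed < 0 or n_failed > n_present:
        raise InconsistentCountsError(
            f"n_failed must lie in [0, n_present]; got {n_failed} of {n_present}"
        )
    return (n_present - n_failed) / n_present


def hearing_from_whisper(left_ear_pass: bool | None, right_ear_pass: bool | None) -> float:
    """Whisper-test hearing-impairment coding.

    Both ears fail -> 1.0 (100% impairment); exactly one fails -> 0.5;
    both pass -> 0.0. Missing ear results raise — never imputed.
    """
    if left_ear_pass is None or right_ear_pass is None:
        missing = [n for n, v in (("left_ear_pass", left_ear_pass),
                                  ("right_ear_pass", right_ear_pass)) if v is None]
        raise MissingDataError(f"whisper-test result missing: {', '.join(missing)}")
    n_failed = int(not left_ear_pass) + int(not right_ear_pass)
    return n_failed / 2.0


def _ears_from_hearing(hearing: float) -> tuple[bool, bool]:
    # Deterministic canonical ear pattern for a given impairment fraction;
    # which ear failed is not modelled.
    if hearing == 1.0:
        return (False, False)
    if hearing == 0.5:
        return (True, False)
    return (True, True)


@dataclass(frozen=True)
class ParticipantProfile:
    """One participant's demographic, clinical, and barrier-score predictors."""

    participant_id: str
    age: int
    sex: str                        # "female" | "male"
    medication_count: int
    medical_history_count: int
    cognitive_score: float          # SMAT, percent 0-100
    physical_score: float           # SMAT, percent 0-100
    smat_vision_score: float        # SMAT, percent 0-100
    dltv_summary_vision_score: float
    seams_score: float
    mped_busyness_score: float
    mped_routine_score: float
    hearing_impairment: float       # in {0.0, 0.5, 1.0}
    cohort: str = "training"
    left_ear_pass: bool | None = None
    right_ear_pass: bool | None = None

    def __post_init__(self):
        for f in fields(self):
            if f.name in ("left_ear_pass", "right_ear_pass"):
                continue
            if getattr(self, f.name) is None:
                raise MissingDataError(f"profile field missing: {f.name}")
        if self.age < 60:
            raise SchemaError(f"age must be >= 60, got {self.age}")
        if self.sex not in SEX_CODES:
            raise SchemaError(f"sex must be one of {sorted(SEX_CODES)}, got {self.sex!r}")
        for name in ("cognitive_score", "physical_score", "smat_vision_score"):
            v = getattr(self, name)
            if not math.isfinite(v) or not (0.0 <= v <= 100.0):
                raise SchemaError(f"{name} must be a percent in [0, 100], got {v}")
        for name in ("dltv_summary_vision_score", "seams_score",
                     "mped_busyness_score", "mped_routine_score"):
            if not math.isfinite(getattr(self, name)):
                raise SchemaError(f"{name} must be finite")
        if self.dltv_summary_vision_score < 0:
            raise SchemaError("dltv_summary_vision_score must be >= 0")
        if self.hearing_impairment not in (0.0, 0.5, 1.0):
            raise SchemaError(
                f"hearing_impairment must be in {{0.0, 0.5, 1.0}}, got {self.hearing_impairment}"
            )
        if self.medication_count < 0 or self.medical_history_count < 0:
            raise SchemaError("medication/medical-history counts must be >= 0")
        if self.cohort not in COHORTS:
            raise SchemaError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.left_ear_pass is None and self.right_ear_pass is None:
            l, r = _ears_from_hearing(self.hearing_impairment)
            object.__setattr__(self, "left_ear_pass", l)
            object.__setattr__(self, "right_ear_pass", r)
        else:
            coded = hearing_from_whisper(self.left_ear_pass, self.right_ear_pass)
            if coded != self.hearing_impairment:
                raise SchemaError(
                    f"{self.participant_id}: hearing_impairment {self.hearing_impairment} "
                    f"inconsistent with whisper results (implies {coded})"
                )

    @property
    def sex_code(self) -> int:
        """0 = female (reference), 1 = male."""
        return SEX_CODES[self.sex]


@dataclass(frozen=True)
class SubtaskOutcome:
    """One (participant, device, subtask) exposure with attempt and failure counts."""

    participant_id: str
    device_id: str
    subtask_code: str
    n_present: int
    n_failed: int

    def __post_init__(self):
        if self.n_present < 1:
            raise InvalidExposureError(
                f"{self.participant_id}/{self.device_id}/{self.subtask_code}: "
                f"n_present must be >= 1, got {self.n_present}"
            )
        if self.n_failed < 0 or self.n_failed > self.n_present:
            raise InconsistentCountsError(
                f"{self.participant_id}/{self.device_id}/{self.subtask_code}: "
                f"n_failed={self.n_failed} outside [0, {self.n_present}]"
            )

    @property
    def n_success(self) -> int:
        return self.n_present - self.n_failed

    @property
    def proportion_success(self) -> float:
        return proportion_subtask_success(self.n_present, self.n_failed)


@dataclass(frozen=True)
class BarrierFlags:
    """Per-domain barrier indicators, each a pure function of one profile."""

    cognitive: bool
    physical: bool
    vision_smat: bool
    vision_dltv: bool
    hearing: bool
    motivation: bool
    environment: bool


def derive_barrier_flags(profile: ParticipantProfile) -> BarrierFlags:
    """Derive barrier flags from instrument cutoffs.

    SMAT domains flag a barrier for low / moderate-to-low scores (<= 84);
    DLTV < 79, SEAMS < 40, MPED busyness >= 15 or routine < 16; hearing flags
    only full (both-ear) impairment.
    """
    return BarrierFlags(
        cognitive=profile.cognitive_score <= SMAT_BARRIER_CUT,
        physical=profile.physical_score <= SMAT_BARRIER_CUT,
        vision_smat=profile.smat_vision_score <= SMAT_BARRIER_CUT,
        vision_dltv=profile.dltv_summary_vision_score < DLTV_BARRIER_CUT,
        hearing=profile.hearing_impairment == 1.0,
        motivation=profile.seams_score < SEAMS_BARRIER_CUT,
        environment=(
            profile.mped_busyness_score >= MPED_BUSYNESS_CUT
            or profile.mped_routine_score < MPED_ROUTINE_CUT
        ),
    )


@dataclass(frozen=True)
class ValidationIssue:
    kind: str       # "duplicate_id" | "referential" | "counts" | "taxonomy"
    message: str


@dataclass
class DatasetReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.passed:
            return "dataset validation: PASS (0 issues)"
        lines = [f"dataset validation: FAIL ({len(self.issues)} issues)"]
        lines += [f"  [{i.kind}] {i.message}" for i in self.issues]
        return "\n".join(lines)


def validate_dataset(
    profiles: Sequence[ParticipantProfile],
    outcomes: Sequence[SubtaskOutcome] | pd.DataFrame,
    taxonomy: Sequence[str] = SUBTASK_CODES,
) -> DatasetReport:
    """Check referential integrity, count invariants, and taxonomy membership.

    Violations are reported, never raised. ``outcomes`` may be a raw DataFrame
    (the on-disk schema) so that count-invariant violations that the
    ``SubtaskOutcome`` constructor would reject can still be itemized.
    """
    report = DatasetReport()
    seen: set[str] = set()
    for p in profiles:
        if p.participant_id in seen:
            report.issues.append(ValidationIssue(
                "duplicate_id", f"participant_id {p.participant_id!r} appears more than once"))
        seen.add(p.participant_id)

    if isinstance(outcomes, pd.DataFrame):
        rows = outcomes[list(OUTCOME_COLUMNS)].itertuples(index=False)
        records = [tuple(r) for r in rows]
    else:
        records = [(o.participant_id, o.device_id, o.subtask_code, o.n_present, o.n_failed)
                   for o in outcomes]

    taxonomy_set = set(taxonomy)
    for pid, dev, code, n_present, n_failed in records:
        where = f"{pid}/{dev}/{code}"
        if pid not in seen:
            report.issues.append(ValidationIssue(
                "referential", f"outcome {where}: unknown participant_id {pid!r}"))
        if code not in taxonomy_set:
            report.issues.append(ValidationIssue(
                "taxonomy", f"outcome {where}: subtask_code {code!r} not in taxonomy"))
        if n_present < 1:
            report.issues.append(ValidationIssue(
                "counts", f"outcome {where}: n_present={n_present} < 1"))
        elif n_failed < 0 or n_failed > n_present:
            report.issues.append(ValidationIssue(
                "counts", f"outcome {where}: n_failed={n_failed} outside [0, {n_present}]"))
    return report


# ---------------------------------------------------------------------------
# CSV schemas (versioned, comma-delimited, "." decimal, UTF-8)
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: Iterable[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "participant_id": p.participant_id,
            "age": p.age,
            "sex": p.sex,
            "medication_count": p.medication_count,
            "medical_history_count": p.medical_history_count,
            "cognitive_score": p.cognitive_score,
            "physical_score": p.physical_score,
            "smat_vision_score": p.smat_vision_score,
            "dltv_summary_vision_score": p.dltv_summary_vision_score,
            "seams_score": p.seams_score,
            "mped_busyness_score": p.mped_busyness_score,
            "mped_routine_score": p.mped_routine_score,
            "hearing_impairment": p.hearing_impairment,
            "left_ear_pass": p.left_ear_pass,
            "right_ear_pass": p.right_ear_pass,
            "cohort": p.cohort,
        })
    return pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS))


def outcomes_to_frame(outcomes: Iterable[SubtaskOutcome]) -> pd.DataFrame:
    rows = [{
        "participant_id": o.participant_id,
        "device_id": o.device_id,
        "subtask_code": o.subtask_code,
        "n_present": o.n_present,
        "n_failed": o.n_failed,
    } for o in outcomes]
    return pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS))


def _check_columns(df: pd.DataFrame, expected: tuple[str, ...], what: str,
                   permissive: bool) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra and not permissive:
        raise SchemaError(
            f"{what}: unknown columns {extra} (schema v{PARTICIPANT_SCHEMA_VERSION}; "
            "pass permissive=True to ignore)"
        )


_BOOL = {"true": True, "false": False, "True": True, "False": False}


def save_participants(profiles: Sequence[ParticipantProfile], path: str | Path) -> None:
    df = profiles_to_frame(profiles)
    df["left_ear_pass"] = df["left_ear_pass"].map({True: "true", False: "false"})
    df["right_ear_pass"] = df["right_ear_pass"].map({True: "true", False: "false"})
    df.to_csv(path, index=False)


def load_participants(path: str | Path, permissive: bool = False) -> list[ParticipantProfile]:
    df = pd.read_csv(path, dtype={"participant_id": str, "device_id": str})
    _check_columns(df, PARTICIPANT_COLUMNS, f"participants table {path}", permissive)
    profiles = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        profiles.append(ParticipantProfile(
            participant_id=str(d["participant_id"]),
            age=int(d["age"]),
            sex=str(d["sex"]),
            medication_count=int(d["medication_count"]),
            medical_history_count=int(d["medical_history_count"]),
            cognitive_score=float(d["cognitive_score"]),
            physical_score=float(d["physical_score"]),
            smat_vision_score=float(d["smat_vision_score"]),
            dltv_summary_vision_score=float(d["dltv_summary_vision_score"]),
            seams_score=float(d["seams_score"]),
            mped_busyness_score=float(d["mped_busyness_score"]),
            mped_routine_score=float(d["mped_routine_score"]),
            hearing_impairment=float(d["hearing_impairment"]),
            cohort=str(d["cohort"]),
            left_ear_pass=_BOOL[str(d["left_ear_pass"])],
            right_ear_pass=_BOOL[str(d["right_ear_pass"])],
        ))
    return profiles


def save_outcomes(outcomes: Sequence[SubtaskOutcome], path: str | Path) -> None:
    outcomes_to_frame(outcomes).to_csv(path, index=False)


def load_outcomes(path: str | Path, permissive: bool = False) -> list[SubtaskOutcome]:
    df = pd.read_csv(path, dtype={"participant_id": str, "device_id": str})
    _check_columns(df, OUTCOME_COLUMNS, f"outcomes table {path}", permissive)
    return [
        SubtaskOutcome(
            participant_id=str(r.participant_id),
            device_id=str(r.device_id),
            subtask_code=str(r.subtask_code),
            n_present=int(r.n_present),
            n_failed=int(r.n_failed),
        )
        for r in df.itertuples(index=False)
    ]
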