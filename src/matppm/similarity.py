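"""Participant-similarity machinery for personalized matching.

Profiles are encoded as standardized feature vectors (z-scores fitted on the
training cohort only) and compared with the cosine similarity metric, which
lands in [-1, 1] once features are centered. The matched subset for a target
participant is the top ``ceil(m * N)`` most similar training participants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError, StateError, UndefinedSimilarityError
from .study_data import ParticipantProfile

log = logging.getLogger(__name__)

VISION_VARIANTS = ("smat", "dltv")

#: Profile fields entering the similarity vector and the GLM, in model order.
#: The vision slot is filled per variant; MPED routine is excluded by default
#: (mirroring the model's predictor list) but can be appended via
#: ``include_mped_routine``.
BASE_FEATURES: tuple[str, ...] = (
    "age", "sex", "medication_count", "medical_history_count",
    "cognitive_score", "physical_score", "VISION", "seams_score",
    "mped_busyness_score", "hearing_impairment",
)
VISION_FIELD = {"smat": "smat_vision_score", "dltv": "dltv_summary_vision_score"}


def feature_fields(vision_variant: str, include_mped_routine: bool = False) -> tuple[str, ...]:
    if vision_variant not in VISION_VARIANTS:
        raise ParameterError(f"vision_variant must be one of {VISION_VARIANTS}")
    names = [VISION_FIELD[vision_variant] if f == "VISION" else f for f in BASE_FEATURES]
    if include_mped_routine:
        names.insert(names.index("hearing_impairment"), "mped_routine_score")
    return tuple(names)


def _raw_value(profile: ParticipantProfile, field: str) -> float:
    if field == "sex":
        return float(profile.sex_code)
    return float(getattr(profile, field))


def raw_feature_matrix(profiles: Sequence[ParticipantProfile],
                       names: Sequence[str]) -> np.ndarray:
    return np.array([[_raw_value(p, f) for f in names] for p in profiles], dtype=float)


@dataclass(frozen=True)
class FeatureVector:
    """A participant's standardized predictor vector."""

    participant_id: str
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.feature_names):
            raise ParameterError("values and feature_names must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"{self.participant_id}: non-finite feature values")


@dataclass(frozen=True)
class ScalingSpec:
    """Per-feature location/scale, estimated on the training cohort only.

    Constant features (zero scale) are dropped with a log entry so that every
    retained scale parameter is strictly positive.
    """

    vision_variant: str
    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    dropped: tuple[str, ...] = ()

    @classmethod
    def fit(cls, profiles: Sequence[ParticipantProfile], vision_variant: str,
            include_mped_routine: bool = False) -> "ScalingSpec":
        if not profiles:
            raise ParameterError("cannot fit a ScalingSpec on an empty cohort")
        names = feature_fields(vision_variant, include_mped_routine)
        mat = raw_feature_matrix(profiles, names)
        center = mat.mean(axis=0)
        scale = mat.std(axis=0)
        keep = scale > 0.0
        dropped = tuple(n for n, k in zip(names, keep) if not k)
        if dropped:
            log.info("ScalingSpec: dropping constant features %s", dropped)
        return cls(
            vision_variant=vision_variant,
            feature_names=tuple(n for n, k in zip(names, keep) if k),
            center=center[keep],
            scale=scale[keep],
            dropped=dropped,
        )

    def standardize(self, field: str, value: float) -> float:
        i = self.feature_names.index(field)
        return (value - self.center[i]) / self.scale[i]

    def transform_profiles(self, profiles: Sequence[ParticipantProfile]) -> np.ndarray:
        mat = raw_feature_matrix(profiles, self.feature_names)
        return (mat - self.center) / self.scale


def encode_features(profile: ParticipantProfile, vision_variant: str,
                    scaling: ScalingSpec) -> FeatureVector:
    """Encode one profile as a standardized feature vector.

    The scaling must come from :meth:`ScalingSpec.fit` on the training cohort;
    the training-mean profile therefore encodes to the zero vector.
    """
    if scaling is None:
        raise StateError("encode_features requires a fitted ScalingSpec")
    if scaling.vision_variant != vision_variant:
        raise ParameterError(
            f"scaling was fitted for variant {scaling.vision_variant!r}, "
            f"requested {vision_variant!r}"
        )
    values = scaling.transform_profiles([profile])[0]
    return FeatureVector(profile.participant_id, values, scaling.feature_names)


def encode_cohort(profiles: Sequence[ParticipantProfile], vision_variant: str,
                  scaling: ScalingSpec) -> tuple[list[str], np.ndarray]:
    """Vectorized encoding of a whole cohort; returns (ids, n x d matrix)."""
    if scaling is None:
        raise StateError("encode_cohort requires a fitted ScalingSpec")
    ids = [p.participant_id for p in profiles]
    return ids, scaling.transform_profiles(profiles)


def cosine_similarity(u: FeatureVector, v: FeatureVector) -> float:
    """Cosine of the angle between two feature vectors, in [-1, 1].

    Symmetric and invariant to positive rescaling; a zero vector has no
    direction and raises rather than silently comparing as 0.
    """
    if u.feature_names != v.feature_names:
        raise ParameterError("feature vectors use different feature lists")
    nu = float(np.linalg.norm(u.values))
    nv = float(np.linalg.norm(v.values))
    if nu == 0.0 or nv == 0.0:
        zero = u.participant_id if nu == 0.0 else v.participant_id
        raise UndefinedSimilarityError(f"zero feature vector for {zero!r}")
    sim = float(np.dot(u.values, v.values) / (nu * nv))
    return max(-1.0, min(1.0, sim))


def matched_subset_size(m: float, n_candidates: int) -> int:
    """Top-m subset size: ceil(m * N), guarded against float grid noise."""
    if not (0.0 < m <= 1.0):
        raise ParameterError(f"matching proportion m must lie in (0, 1], got {m}")
    return math.ceil(m * n_candidates - 1e-9)


def rank_candidates(target_values: np.ndarray, candidate_matrix: np.ndarray,
                    candidate_ids: Sequence[str]) -> list[str]:
    """Candidate ids sorted by descending cosine similarity to the target.

    Ties break on ascending participant_id so runs are bit-reproducible.
    Zero-norm vectors (target or candidate) are undefined and raise.
    """
    tnorm = float(np.linalg.norm(target_values))
    if tnorm == 0.0:
        raise UndefinedSimilarityError("target encodes to the zero vector")
    cnorms = np.linalg.norm(candidate_matrix, axis=1)
    if np.any(cnorms == 0.0):
        bad = [candidate_ids[i] for i in np.nonzero(cnorms == 0.0)[0]]
        raise UndefinedSimilarityError(f"zero feature vector(s) for {bad}")
    sims = candidate_matrix @ target_values / (cnorms * tnorm)
    order = sorted(range(len(candidate_ids)), key=lambda i: (-sims[i], candidate_ids[i]))
    return [candidate_ids[i] for i in order]


def select_matched_subset(target: FeatureVector,
                          candidates: Sequence[FeatureVector],
                          m: float) -> list[str]:
    """Ids of the top m*100% most similar candidates, most similar first.

    The target must not appear among the candidates (self-matching is always
    excluded upstream). ``m = 1.0`` returns every candidate — the
    nonpersonalized pool.
    """
    if not candidates:
        raise ParameterError("candidate pool is empty")
    ids = [c.participant_id for c in candidates]
    if target.participant_id in ids:
        raise ParameterError(
            f"target {target.participant_id!r} must be excluded from its own candidate pool"
        )
    for c in candidates:
        if c.feature_names != target.feature_names:
            raise ParameterError("feature vectors use different feature lists")
    count = matched_subset_size(m, len(candidates))
    matrix = np.vstack([c.values for c in candidates])
    return rank_candidates(target.values, matrix, ids)[:count]


def similarity_table(target: FeatureVector,
                     candidates: Sequence[FeatureVector]):
    """Long-format (target_id, candidate_id, similarity) table for audit export."""
    import pandas as pd

    rows = [
        {"target_id": target.participant_id,
         "candidate_id": c.participant_id,
         "similarity": cosine_similarity(target, c)}
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=["target_id", "candidate_id", "similarity"])
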