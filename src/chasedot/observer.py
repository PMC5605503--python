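"""Synthetic observers: the generative accuracy model and heuristic watchers.

Two complementary response generators are provided.

The *parametric* generator reproduces the statistical structure the study's
mixed-model analysis assumes: trial accuracy is Bernoulli with a logit that
is linear in Group (ASD = 1, TD = 0), Age (years), Trial type (chase-present
= 1), Subtlety (deg), condition dummies (social / non-social against the
baseline), a Group × Subtlety interaction, plus a Normal(0, σ_u) per-
participant random intercept. The default coefficients are the study's
fitted estimates, so simulated cohorts show the same qualitative pattern:
accuracy falls with subtlety, the social cue helps, the non-social cue
barely does, and the ASD group depends less on subtlety than the TD group.

The *heuristic* observer operationalizes the item-by-item visual-search
account of chase detection: it scores every ordered pair of visible dots on
heading alignment, closing proximity and (when available) cue consistency,
and reports a chase when the best pair's score exceeds a noisy criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats
from scipy.special import expit

from .cues import PAIR_FREQ_HZ, CueTrack
from .exceptions import ConsistencyError, InvalidParameterError, InvalidPairError
from .stimulus import Trajectory

__all__ = [
    "ParticipantProfile",
    "GlmmParams",
    "ResponseRecord",
    "ObserverParams",
    "ChaseScores",
    "sample_cohort",
    "cohort_frame",
    "response_probability",
    "simulate_study",
    "chase_statistics",
    "heuristic_observer_response",
]

#: Cohort age structure: (mean, SD) in years, per group, and truncation range.
ASD_AGE = (14.08, 1.47)
TD_AGE = (14.33, 1.27)
AGE_RANGE = (12.0, 16.5)


@dataclass(frozen=True)
class GlmmParams:
    """Fixed effects (logit units) and random-intercept SD of the accuracy
    model. Defaults are the study's fitted estimates; ``sigma_u`` was not
    reported and defaults to 0.8 logits."""

    beta_intercept: float = -1.13
    beta_group: float = -0.39
    beta_age: float = 0.17  # per year
    beta_trialtype: float = 0.23  # chase-present = 1
    beta_subtlety: float = -0.05  # per deg
    beta_social: float = 0.66
    beta_nonsocial: float = 0.15
    beta_group_x_subtlety: float = 0.01  # per deg
    sigma_u: float = 0.8

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise InvalidParameterError("sigma_u must be non-negative")

    def fixed_effects(self) -> dict[str, float]:
        return {
            "intercept": self.beta_intercept,
            "group": self.beta_group,
            "age": self.beta_age,
            "trial_type": self.beta_trialtype,
            "subtlety": self.beta_subtlety,
            "social": self.beta_social,
            "nonsocial": self.beta_nonsocial,
            "group_x_subtlety": self.beta_group_x_subtlety,
        }


@dataclass(frozen=True)
class ParticipantProfile:
    """One synthetic participant: group (TD=0, ASD=1), age in years, and the
    random intercept u (logit units)."""

    participant_id: int
    group: int
    age: float
    random_intercept: float


@dataclass
class ResponseRecord:
    """Outcome of one detection trial."""

    participant_id: int | None
    condition: str
    subtlety: float
    chase_present: bool
    response_present: bool
    correct: bool
    quadrant_response: int | None = None

    def __post_init__(self) -> None:
        if self.correct != (self.response_present == self.chase_present):
            raise ConsistencyError("correct must equal (response == presence)")


@dataclass(frozen=True)
class ObserverParams:
    """Weights and decision parameters of the heuristic pair-search observer."""

    w_alignment: float = 1.0
    w_proximity: float = 0.0
    w_cue: float = 0.0
    criterion: float = 0.5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")


def sample_cohort(
    n_per_group: int,
    params: GlmmParams,
    rng: np.random.Generator,
    asd_age: tuple[float, float] = ASD_AGE,
    td_age: tuple[float, float] = TD_AGE,
    age_range: tuple[float, float] = AGE_RANGE,
) -> list[ParticipantProfile]:
    """Draw a matched cohort: ``n_per_group`` ASD plus ``n_per_group`` TD.

    Ages come from group-specific normals truncated to ``age_range``
    (defaults match the study cohort); random intercepts are
    Normal(0, sigma_u). TD participants come first (ids 0..n−1).
    """
    if n_per_group < 1:
        raise InvalidParameterError("n_per_group must be at least 1")
    profiles = []
    pid = 0
    for group, (mean, sd) in ((0, td_age), (1, asd_age)):
        a = (age_range[0] - mean) / sd
        b = (age_range[1] - mean) / sd
        ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                   size=n_per_group, random_state=rng)
        us = (rng.normal(0.0, params.sigma_u, size=n_per_group)
              if params.sigma_u > 0 else np.zeros(n_per_group))
        for age, u in zip(ages, us):
            profiles.append(ParticipantProfile(pid, group, float(age), float(u)))
            pid += 1
    return profiles


def cohort_frame(cohort: Sequence[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in cohort],
            "group": [p.group for p in cohort],
            "age": [p.age for p in cohort],
            "random_intercept": [p.random_intercept for p in cohort],
        }
    )


def _linear_predictor(
    group: np.ndarray,
    age: np.ndarray,
    present: np.ndarray,
    subtlety: np.ndarray,
    condition: np.ndarray,
    u: np.ndarray,
    params: GlmmParams,
) -> np.ndarray:
    return (
        params.beta_intercept
        + params.beta_group * group
        + params.beta_age * age
        + params.beta_trialtype * present
        + params.beta_subtlety * subtlety
        + params.beta_social * (condition == "social")
        + params.beta_nonsocial * (condition == "nonsocial")
        + params.beta_group_x_subtlety * group * subtlety
        + u
    )


def response_probability(
    profile: ParticipantProfile,
    trial: Mapping,
    params: GlmmParams,
) -> float:
    """P(correct) for one participant on one trial: the inverse logit of the
    accuracy model's linear predictor including the random intercept."""
    eta = _linear_predictor(
        np.asarray(float(profile.group)),
        np.asarray(profile.age),
        np.asarray(float(bool(trial["chase_present"]))),
        np.asarray(float(trial["subtlety"])),
        np.asarray(trial["condition"]),
        np.asarray(profile.random_intercept),
        params,
    )
    return float(expit(eta))


def simulate_study(
    design: pd.DataFrame,
    cohort: Sequence[ParticipantProfile],
    params: GlmmParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate one trial-by-trial response table for a whole cohort.

    One record per non-practice design row: ``correct`` is Bernoulli with
    the model's probability, ``response_present`` is derived from ``correct``
    and the trial's true presence, and a quadrant click is logged (uniform
    over quadrants, bookkeeping only) whenever the response is "present" on
    a chase-present trial.
    """
    design_ids = set(design["participant_id"].unique())
    cohort_ids = {p.participant_id for p in cohort}
    if design_ids != cohort_ids:
        raise ConsistencyError(
            "design and cohort cover different participants: "
            f"{sorted(design_ids ^ cohort_ids)[:5]}..."
        )
    test = design.loc[~design["is_practice"]].reset_index(drop=True)
    merged = test.merge(cohort_frame(cohort), on="participant_id", how="left")
    eta = _linear_predictor(
        merged["group"].to_numpy(float),
        merged["age"].to_numpy(float),
        merged["chase_present"].to_numpy(float),
        merged["subtlety"].to_numpy(float),
        merged["condition"].to_numpy(),
        merged["random_intercept"].to_numpy(float),
        params,
    )
    p = expit(eta)
    correct = rng.random(len(merged)) < p
    present = merged["chase_present"].to_numpy(bool)
    response_present = np.where(correct, present, ~present)
    quadrant = np.where(
        response_present & present, rng.integers(1, 5, size=len(merged)), 0
    )
    out = merged[
        ["participant_id", "group", "age", "condition", "subtlety", "chase_present"]
    ].copy()
    out["response_present"] = response_present
    out["correct"] = correct
    out["quadrant"] = pd.array(
        np.where(quadrant > 0, quadrant, pd.NA), dtype="Int64"
    )
    return out


@dataclass
class ChaseScores:
    """Chase-evidence statistics for one ordered (wolf, sheep) candidate pair."""

    heading_alignment: float
    proximity: float
    cue_consistency: float | None = None

    def combined(self, params: ObserverParams) -> float:
        score = (params.w_alignment * self.heading_alignment
                 + params.w_proximity * self.proximity)
        if self.cue_consistency is not None:
            score += params.w_cue * self.cue_consistency
        return score


def chase_statistics(
    traj: Trajectory,
    cues: CueTrack | None,
    ordered_pair: tuple[int, int],
) -> ChaseScores:
    """Score an ordered (candidate wolf, candidate sheep) pair of visible dots.

    * heading_alignment — mean over frames of cos(candidate wolf heading −
      bearing to candidate sheep); 1 for perfect heat-seeking, ~0 for
      independent walkers.
    * proximity — negative slope of the pair distance over time (per s),
      normalized by the mean distance; positive when the pair closes.
    * cue_consistency — with a gaze track, mean cos(gaze − bearing); with a
      luminance track, magnitude-squared coherence of the two dots' signals
      at the pair modulation frequency (3 Hz).
    """
    w, s = ordered_pair
    visible = set(traj.visible_indices)
    if w not in visible or s not in visible or w == s:
        raise InvalidPairError(f"invalid visible ordered pair {ordered_pair}")
    d = traj.positions[:, s, :] - traj.positions[:, w, :]
    bearing = np.arctan2(d[:, 1], d[:, 0])
    heading = np.radians(traj.headings[:, w])
    alignment = float(np.mean(np.cos(heading - bearing)))

    dist = np.hypot(d[:, 0], d[:, 1])
    t = np.arange(traj.n_frames) / traj.config.frame_rate
    slope = float(np.polyfit(t, dist, 1)[0])
    proximity = -slope / float(np.mean(dist))

    cue_score: float | None = None
    if cues is not None:
        if cues.kind == "gaze":
            gaze = np.radians(cues.values[:, w])
            cue_score = float(np.mean(np.cos(gaze - bearing)))
        elif cues.kind == "luminance":
            fs = traj.config.frame_rate
            f, cxy = sp_signal.coherence(
                cues.values[:, w], cues.values[:, s], fs=fs,
                nperseg=min(64, traj.n_frames),
            )
            cue_score = float(cxy[np.argmin(np.abs(f - PAIR_FREQ_HZ))])
    return ChaseScores(alignment, proximity, cue_score)


def heuristic_observer_response(
    traj: Trajectory,
    cues: CueTrack | None,
    params: ObserverParams,
    rng: np.random.Generator,
    participant_id: int | None = None,
) -> ResponseRecord:
    """One trial decision of the pair-search observer.

    Scores all 12 ordered visible pairs, adds Gaussian decision noise to the
    maximum, and reports a chase if it clears the criterion. The quadrant
    response is the quadrant of the best pair's candidate sheep at the final
    frame (1 = upper-right, counterclockwise), logged only for "present"
    responses on chase-present trials.
    """
    best_score = -np.inf
    best_pair: tuple[int, int] | None = None
    for w in traj.visible_indices:
        for s in traj.visible_indices:
            if w == s:
                continue
            score = chase_statistics(traj, cues, (w, s)).combined(params)
            if score > best_score:
                best_score, best_pair = score, (w, s)
    noisy = best_score + (rng.normal(0.0, params.noise_sd) if params.noise_sd else 0.0)
    response_present = bool(noisy > params.criterion)
    quadrant = None
    if response_present and traj.spec.chase_present and best_pair is not None:
        x, y = traj.positions[-1, best_pair[1], :]
        quadrant = {(True, True): 1, (False, True): 2,
                    (False, False): 3, (True, False): 4}[(x >= 0, y >= 0)]
    return ResponseRecord(
        participant_id=participant_id,
        condition=traj.spec.condition,
        subtlety=traj.spec.subtlety,
        chase_present=traj.spec.chase_present,
        response_present=response_present,
        correct=response_present == traj.spec.chase_present,
        quadrant_response=quadrant,
    )
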