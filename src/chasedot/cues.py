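"""Condition-specific cue signals layered on top of a trajectory.

Social condition: every dot carries "eyes"; the wolf's eyes point at the
sheep on chase-present trials, all other eyes follow their dot's own heading.

Non-social condition: dot color/contrast is modulated sinusoidally. On
chase-present trials wolf and sheep share a 3 Hz modulation (offset by 0.15
rad in phase) while the two distractors modulate at 0.5 Hz; on chase-absent
trials the wolf is paired with one randomly chosen visible distractor at
3 Hz so that counting modulation frequencies alone cannot solve the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConditionMismatchError
from .stimulus import Trajectory, wrap_deg

__all__ = ["CueTrack", "eye_track", "color_track"]

#: Modulation frequency (Hz) shared by the wolf and its partner dot.
PAIR_FREQ_HZ = 3.0
#: Modulation frequency (Hz) of the unpaired distractor dots.
DISTRACTOR_FREQ_HZ = 0.5
#: Phase offset (radians) between the two paired same-frequency dots.
PAIR_PHASE_OFFSET = 0.15
#: Modulation amplitude (dimensionless luminance units).
AMPLITUDE = 1.0


@dataclass
class CueTrack:
    """Per-frame, per-dot cue values for one trial.

    ``values`` is ``(n_frames, n_dots)``; gaze entries are orientations in
    degrees wrapped to [0, 360), luminance entries are dimensionless in
    [−amplitude, amplitude]. Columns for the invisible dot are NaN.
    """

    kind: str  # {"gaze", "luminance"}
    values: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def eye_track(traj: Trajectory) -> CueTrack:
    """Gaze-orientation track for a social-condition trial.

    Chase-present: the wolf's gaze equals the instantaneous wolf→sheep
    bearing on every frame; every other visible dot gazes along its own
    heading. Chase-absent: all visible dots (including the wolf) gaze along
    their own heading, so gaze statistics carry no trace of the invisible
    target.
    """
    if traj.spec.condition != "social":
        raise ConditionMismatchError(
            f"eye_track requires a social trial, got {traj.spec.condition!r}"
        )
    values = traj.headings.copy()
    if traj.spec.chase_present:
        w, s = traj.wolf_index, traj.sheep_index
        d = traj.positions[:, s, :] - traj.positions[:, w, :]
        values[:, w] = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0
    for i, role in enumerate(traj.roles):
        if role == "invisible_sheep":
            values[:, i] = np.nan
    return CueTrack(kind="gaze", values=values)


def color_track(traj: Trajectory, rng: np.random.Generator | None = None) -> CueTrack:
    """Sinusoidal luminance-modulation track for a non-social trial.

    Each visible dot i carries ``L_i(t) = A sin(2π f_i t + φ_i)``. The wolf
    and its partner (the sheep when present, otherwise a randomly chosen
    visible distractor) share ``f = 3 Hz`` with a 0.15 rad phase offset;
    remaining dots run at 0.5 Hz with independent uniform phases.
    """
    if traj.spec.condition != "nonsocial":
        raise ConditionMismatchError(
            f"color_track requires a nonsocial trial, got {traj.spec.condition!r}"
        )
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=traj.spec.seed, spawn_key=(0xC0E,))
        )
    n_dots = traj.n_dots
    w = traj.wolf_index
    if traj.spec.chase_present:
        partner = traj.sheep_index
    else:
        distractors = [i for i, r in enumerate(traj.roles) if r == "distractor"]
        partner = int(rng.choice(distractors))

    freqs = np.full(n_dots, DISTRACTOR_FREQ_HZ)
    freqs[w] = freqs[partner] = PAIR_FREQ_HZ
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_dots)
    phases[partner] = phases[w] + PAIR_PHASE_OFFSET

    t = np.arange(traj.n_frames) / traj.config.frame_rate
    values = AMPLITUDE * np.sin(2.0 * np.pi * freqs[None, :] * t[:, None]
                                + phases[None, :])
    for i, role in enumerate(traj.roles):
        if role == "invisible_sheep":
            values[:, i] = np.nan
            freqs[i] = np.nan
            phases[i] = np.nan
    return CueTrack(
        kind="luminance",
        values=values,
        params={
            "frequencies_hz": freqs.tolist(),
            "phases_rad": phases.tolist(),
            "amplitude": AMPLITUDE,
            "partner": partner,
        },
    )
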