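"""Trajectory simulation for the chase-detection display.

A trial shows four identical dots moving at constant speed in a rectangular
arena. Three dots move haphazardly, resampling their heading within a fixed
angular window at regular update events. The fourth dot, the *wolf*, pursues
a *sheep*: at each of its update events (after a short onset delay) it draws
a heading uniformly within ``±subtlety`` degrees of the instantaneous bearing
to the sheep. In chase-present trials the sheep is one of the visible dots;
in chase-absent trials the wolf pursues a fifth, invisible dot, so the
visible display contains no detectable chase.

Two hard constraints are enforced on every frame: the wolf–sheep distance
never drops below a floor (default 5 deg) and no pair of dots may overlap
(center distance below one dot diameter). When a sampled heading would
violate a constraint, the dot keeps its previous heading instead; if that
also violates, it steers directly away from the nearest offender.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .exceptions import (
    DegenerateGeometryError,
    InitializationError,
    InvalidParameterError,
)

__all__ = [
    "SimConfig",
    "TrialSpec",
    "DotState",
    "Trajectory",
    "sample_random_heading",
    "sample_wolf_heading",
    "advance_dot",
    "resolve_constraints",
    "simulate_trial",
    "wrap_deg",
    "signed_delta_deg",
    "bearing_deg",
]

CONDITIONS = ("baseline", "social", "nonsocial")

#: Dot roles. ``invisible_sheep`` only appears in chase-absent trials.
ROLES = ("wolf", "sheep", "distractor", "invisible_sheep")


def wrap_deg(angle: float) -> float:
    """Wrap an angle (deg) to [0, 360)."""
    return angle % 360.0


def signed_delta_deg(a: float, b: float) -> float:
    """Signed angular difference a − b (deg), wrapped to [−180, 180)."""
    return (a - b + 180.0) % 360.0 - 180.0


def bearing_deg(from_xy: tuple[float, float], to_xy: tuple[float, float]) -> float:
    """Bearing (deg, 0 = +x, counterclockwise) from one point to another."""
    dx = to_xy[0] - from_xy[0]
    dy = to_xy[1] - from_xy[1]
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("bearing undefined for coincident points")
    return math.degrees(math.atan2(dy, dx)) % 360.0


@dataclass(frozen=True)
class SimConfig:
    """Kinematic and display constants of the paradigm.

    Defaults follow the study display: 60 Hz refresh, 3000 ms trials,
    14.5 deg/s dot speed, 1 deg dots, 120 deg heading-resampling window for
    random motion, direction updates roughly every 170 ms, a 5 deg wolf–sheep
    distance floor, and a 170 ms delay before the wolf starts chasing.
    The arena is the one free parameter the display leaves open; the default
    48 × 30 deg corresponds to a 24-inch 16:10 monitor viewed at 57 cm.
    """

    frame_rate: float = 60.0  # Hz
    trial_duration: float = 3000.0  # ms
    dot_speed: float = 14.5  # deg visual angle / s
    dot_diameter: float = 1.0  # deg
    random_window: float = 120.0  # deg, full width
    direction_update_interval: float = 170.0  # ms
    wolf_sheep_min_dist: float = 5.0  # deg
    chase_onset_delay: float = 170.0  # ms
    arena_width: float = 48.0  # deg
    arena_height: float = 30.0  # deg
    boundary_mode: str = "reflect"  # {reflect, resample}

    def __post_init__(self) -> None:
        positive = (
            "frame_rate", "trial_duration", "dot_speed", "dot_diameter",
            "random_window", "direction_update_interval",
            "arena_width", "arena_height",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.wolf_sheep_min_dist <= self.dot_diameter:
            raise InvalidParameterError(
                "wolf_sheep_min_dist must exceed dot_diameter"
            )
        if self.chase_onset_delay < 0:
            raise InvalidParameterError("chase_onset_delay must be non-negative")
        if self.random_window > 360.0:
            raise InvalidParameterError("random_window cannot exceed 360 deg")
        if self.boundary_mode not in ("reflect", "resample"):
            raise InvalidParameterError(
                f"unknown boundary_mode {self.boundary_mode!r}"
            )

    @property
    def n_frames(self) -> int:
        return round(self.trial_duration * self.frame_rate / 1000.0)

    @property
    def frame_step(self) -> float:
        """Per-frame displacement magnitude (deg)."""
        return self.dot_speed / self.frame_rate

    @property
    def update_interval_frames(self) -> int:
        return max(1, round(self.direction_update_interval * self.frame_rate / 1000.0))

    @property
    def chase_onset_frames(self) -> int:
        return round(self.chase_onset_delay * self.frame_rate / 1000.0)


@dataclass(frozen=True)
class TrialSpec:
    """One trial: cue condition, chasing subtlety, chase presence, seed.

    ``subtlety`` is the half-width (deg) of the wolf's heading window around
    the bearing to the sheep; the study used 15, 45 and 75.
    """

    condition: str
    subtlety: float
    chase_present: bool
    seed: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidParameterError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.subtlety <= 180.0:
            raise InvalidParameterError("subtlety must be in [0, 180] deg")


@dataclass
class DotState:
    """Snapshot of a single dot: position (deg), heading (deg), role."""

    position: tuple[float, float]
    heading: float
    role: str
    next_update_frame: int = 0


@dataclass
class Trajectory:
    """Full per-frame record of one simulated trial.

    Arrays are indexed ``[frame, dot]``; dot order is sheep (visible or
    invisible) first, then distractors, then the wolf last. ``update_log``
    marks heading-resampling events, ``override_log`` frames where a
    constraint forced a heading different from the sampled/held one, and
    ``reflect_log`` frames with an arena-boundary event.
    """

    positions: np.ndarray  # (F, D, 2) float
    headings: np.ndarray  # (F, D) float, deg in [0, 360)
    roles: tuple[str, ...]
    update_log: np.ndarray  # (F, D) bool
    override_log: np.ndarray  # (F, D) bool
    reflect_log: np.ndarray  # (F, D) bool
    spec: TrialSpec
    config: SimConfig

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    @property
    def wolf_index(self) -> int:
        return self.roles.index("wolf")

    @property
    def sheep_index(self) -> int:
        """Index of the wolf's target (visible sheep or invisible fifth dot)."""
        role = "sheep" if self.spec.chase_present else "invisible_sheep"
        return self.roles.index(role)

    @property
    def visible_indices(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.roles) if r != "invisible_sheep")

    def dot_states(self, frame: int) -> list[DotState]:
        K = self.config.update_interval_frames
        out = []
        for d in range(self.n_dots):
            later = np.flatnonzero(self.update_log[frame + 1 :, d])
            nxt = frame + 1 + int(later[0]) if later.size else frame + K
            out.append(
                DotState(
                    position=(float(self.positions[frame, d, 0]),
                              float(self.positions[frame, d, 1])),
                    heading=float(self.headings[frame, d]),
                    role=self.roles[d],
                    next_update_frame=nxt,
                )
            )
        return out

    def pair_distances(self, i: int, j: int) -> np.ndarray:
        """Per-frame center-to-center distance between dots i and j."""
        d = self.positions[:, i, :] - self.positions[:, j, :]
        return np.hypot(d[:, 0], d[:, 1])

    def wolf_sheep_distances(self) -> np.ndarray:
        return self.pair_distances(self.wolf_index, self.sheep_index)

    def frame_displacements(self) -> np.ndarray:
        """Per-frame chord displacement of each dot, shape (F−1, D).

        On frames with a boundary reflection the chord is shorter than the
        path length (the dot travels a bent two-segment path of full length
        ``frame_step``); use ``reflect_log`` to identify those frames.
        """
        d = np.diff(self.positions, axis=0)
        return np.hypot(d[..., 0], d[..., 1])

    def wolf_update_deviations(self) -> np.ndarray:
        """Signed deviation (deg) of the wolf's heading from the bearing to
        the sheep at each override-free wolf update event after chase onset.

        The bearing is taken from the wolf's pre-step position to the sheep's
        position on the update frame, matching the sampling geometry (the
        sheep advances before the wolf within a frame).
        """
        w, s = self.wolf_index, self.sheep_index
        onset = self.config.chase_onset_frames
        devs = []
        for t in np.flatnonzero(self.update_log[:, w]):
            if t < onset or self.override_log[t, w] or self.reflect_log[t, w]:
                continue
            b = bearing_deg(tuple(self.positions[t - 1, w]),
                            tuple(self.positions[t, s]))
            devs.append(signed_delta_deg(float(self.headings[t, w]), b))
        return np.asarray(devs)

    def distractor_turn_angles(self) -> np.ndarray:
        """Signed heading changes (deg) of distractors at their override-free
        update events."""
        turns = []
        for d, role in enumerate(self.roles):
            if role != "distractor":
                continue
            for t in np.flatnonzero(self.update_log[:, d]):
                if self.override_log[t, d] or self.reflect_log[t, d]:
                    continue
                turns.append(
                    signed_delta_deg(float(self.headings[t, d]),
                                     float(self.headings[t - 1, d]))
                )
        return np.asarray(turns)

    def turn_angles(self, dot: int) -> np.ndarray:
        """Signed heading changes of one dot at its override-free updates."""
        out = []
        for t in np.flatnonzero(self.update_log[:, dot]):
            if self.override_log[t, dot] or self.reflect_log[t, dot]:
                continue
            out.append(signed_delta_deg(float(self.headings[t, dot]),
                                        float(self.headings[t - 1, dot])))
        return np.asarray(out)


# ---------------------------------------------------------------------------
# sampling primitives

def sample_random_heading(prev_heading: float, window: float, rng: np.random.Generator) -> float:
    """Draw a new heading uniformly within ``±window/2`` of the previous one.

    This is the haphazard-motion rule of the distractor dots (and of the wolf
    before chase onset), with the study's 120 deg full window by default.
    """
    if window <= 0:
        raise InvalidParameterError("window must be positive")
    if window > 360:
        raise InvalidParameterError("window cannot exceed 360 deg")
    return wrap_deg(prev_heading + rng.uniform(-window / 2.0, window / 2.0))


def sample_wolf_heading(
    wolf_pos: tuple[float, float],
    sheep_pos: tuple[float, float],
    subtlety: float,
    rng: np.random.Generator,
) -> float:
    """Draw a wolf heading uniformly within ``±subtlety`` of the bearing to
    the sheep (the chasing-subtlety manipulation; 0 = perfect heat-seeking)."""
    b = bearing_deg(wolf_pos, sheep_pos)
    if subtlety == 0.0:
        return b
    return wrap_deg(b + rng.uniform(-subtlety, subtlety))


def _step_position(
    x: float,
    y: float,
    heading: float,
    step: float,
    half_w: float,
    half_h: float,
    mode: str,
    rng: np.random.Generator | None,
) -> tuple[float, float, float, bool]:
    """Advance one step, resolving boundary events.

    Returns (x, y, heading, boundary_hit). ``reflect`` mirrors position and
    velocity at the wall; ``resample`` redraws a uniform heading until the
    step stays inside (requires an rng).
    """
    h = math.radians(heading)
    nx = x + step * math.cos(h)
    ny = y + step * math.sin(h)
    if -half_w <= nx <= half_w and -half_h <= ny <= half_h:
        return nx, ny, heading, False
    if mode == "resample":
        if rng is None:
            raise InvalidParameterError("resample boundary mode requires an rng")
        for _ in range(1000):
            cand = rng.uniform(0.0, 360.0)
            hr = math.radians(cand)
            cx = x + step * math.cos(hr)
            cy = y + step * math.sin(hr)
            if -half_w <= cx <= half_w and -half_h <= cy <= half_h:
                return cx, cy, cand, True
        raise InitializationError("could not resample an in-bounds heading")
    # specular reflection; a second pass covers corner hits
    dx, dy = math.cos(h), math.sin(h)
    for _ in range(2):
        if nx > half_w:
            nx = 2 * half_w - nx
            dx = -dx
        elif nx < -half_w:
            nx = -2 * half_w - nx
            dx = -dx
        if ny > half_h:
            ny = 2 * half_h - ny
            dy = -dy
        elif ny < -half_h:
            ny = -2 * half_h - ny
            dy = -dy
        if -half_w <= nx <= half_w and -half_h <= ny <= half_h:
            break
    return nx, ny, math.degrees(math.atan2(dy, dx)) % 360.0, True


def advance_dot(
    state: DotState,
    speed: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> DotState:
    """Move a dot one frame along its heading at the given speed (deg/s).

    The heading is unchanged unless the step hits an arena wall, in which
    case the configured boundary mode applies.
    """
    half_w = config.arena_width / 2.0 - config.dot_diameter / 2.0
    half_h = config.arena_height / 2.0 - config.dot_diameter / 2.0
    x, y, h, _ = _step_position(
        state.position[0], state.position[1], state.heading,
        speed / config.frame_rate, half_w, half_h, config.boundary_mode, rng,
    )
    return DotState(position=(x, y), heading=h, role=state.role,
                    next_update_frame=state.next_update_frame)


def _constraint_margin(
    next_pos: tuple[float, float],
    is_wolf: bool,
    sheep_pos: tuple[float, float] | None,
    other_positions: Sequence[tuple[float, float]],
    config: SimConfig,
) -> float:
    """Worst slack (deg) over all distance constraints for a candidate
    position; negative means a violation."""
    margin = math.inf
    for ox, oy in other_positions:
        margin = min(margin,
                     math.hypot(next_pos[0] - ox, next_pos[1] - oy) - config.dot_diameter)
    if is_wolf and sheep_pos is not None:
        margin = min(
            margin,
            math.hypot(next_pos[0] - sheep_pos[0], next_pos[1] - sheep_pos[1])
            - config.wolf_sheep_min_dist,
        )
    return margin


def _resolve_heading(
    proposed: float,
    prev_heading: float,
    pos: tuple[float, float],
    is_wolf: bool,
    sheep_pos: tuple[float, float] | None,
    other_positions: Sequence[tuple[float, float]],
    config: SimConfig,
    half_w: float,
    half_h: float,
    rng: np.random.Generator | None,
) -> tuple[float, bool]:
    """Apply the minimum-distance and non-overlap rules to a proposed heading.

    Order of fallbacks: proposed heading → previous heading (the display's
    documented behavior) → heading directly away from the nearest offender →
    exhaustive 1-deg grid maximizing the worst constraint margin.
    """
    step = config.frame_step

    def margin_of(heading: float) -> float:
        nx, ny, _, _ = _step_position(pos[0], pos[1], heading, step,
                                      half_w, half_h, config.boundary_mode, rng)
        return _constraint_margin((nx, ny), is_wolf, sheep_pos,
                                  other_positions, config)

    if margin_of(proposed) >= 0.0:
        return proposed, False
    if margin_of(prev_heading) >= 0.0:
        return prev_heading, True
    # steer directly away from the nearest constrained object
    nearest = None
    best = math.inf
    for ox, oy in other_positions:
        d = math.hypot(pos[0] - ox, pos[1] - oy)
        if d < best:
            best, nearest = d, (ox, oy)
    if is_wolf and sheep_pos is not None:
        d = math.hypot(pos[0] - sheep_pos[0], pos[1] - sheep_pos[1])
        # distance floor is the binding constraint well before overlap is
        if d - config.wolf_sheep_min_dist < best - config.dot_diameter:
            nearest = sheep_pos
    if nearest is not None and (pos[0] != nearest[0] or pos[1] != nearest[1]):
        away = bearing_deg(nearest, pos)
        if margin_of(away) >= 0.0:
            return away, True
    best_h, best_m = prev_heading, -math.inf
    for h in range(0, 360):
        m = margin_of(float(h))
        if m > best_m:
            best_h, best_m = float(h), m
    return best_h, True


def resolve_constraints(
    proposed_heading: float,
    dot: DotState,
    others: Sequence[DotState],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Public constraint resolver operating on :class:`DotState` snapshots.

    The wolf additionally enforces the distance floor against the sheep
    (visible or invisible) found among ``others``.
    """
    half_w = config.arena_width / 2.0 - config.dot_diameter / 2.0
    half_h = config.arena_height / 2.0 - config.dot_diameter / 2.0
    sheep_pos = None
    if dot.role == "wolf":
        for o in others:
            if o.role in ("sheep", "invisible_sheep"):
                sheep_pos = o.position
                break
    return _resolve_heading(
        proposed_heading, dot.heading, dot.position, dot.role == "wolf",
        sheep_pos, [o.position for o in others], config, half_w, half_h, rng,
    )


def _initial_positions(
    n_dots: int,
    wolf: int,
    sheep: int,
    config: SimConfig,
    rng: np.random.Generator,
    max_retries: int = 10_000,
) -> list[tuple[float, float]]:
    half_w = config.arena_width / 2.0 - config.dot_diameter / 2.0
    half_h = config.arena_height / 2.0 - config.dot_diameter / 2.0
    for _ in range(max_retries):
        xs = rng.uniform(-half_w, half_w, size=n_dots)
        ys = rng.uniform(-half_h, half_h, size=n_dots)
        ok = True
        for i in range(n_dots):
            for j in range(i + 1, n_dots):
                d = math.hypot(xs[i] - xs[j], ys[i] - ys[j])
                if d < config.dot_diameter:
                    ok = False
                    break
                if {i, j} == {wolf, sheep} and d <= config.wolf_sheep_min_dist:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return [(float(x), float(y)) for x, y in zip(xs, ys)]
    raise InitializationError(
        f"no valid initial placement found in {max_retries} attempts"
    )


def simulate_trial(
    spec: TrialSpec,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    max_trial_retries: int = 50,
) -> Trajectory:
    """Simulate one trial and return its full :class:`Trajectory`.

    All randomness derives from ``spec.seed`` (one sub-stream per dot plus
    one for initialization), so identical (spec, config) pairs reproduce
    bit-identical trajectories. Within each frame dots advance sequentially
    — the wolf's target first, the wolf last — so every constraint is checked
    against the positions the display would actually show on that frame.

    Trajectories are generated so that the distance floor and non-overlap
    rules hold on every frame: the per-frame steering rules enforce them
    locally, and the rare trajectory in which a wall-pinned dot is still
    cornered into a violation (under 1% of trials) is discarded and
    regenerated from a deterministically derived retry seed.

    The ``rng`` argument, if given, replaces the seed-derived initialization
    stream (dot sub-streams still come from the seed).
    """
    config = config or SimConfig()
    root = np.random.SeedSequence(spec.seed)
    for attempt in range(max_trial_retries):
        ss = root if attempt == 0 else np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(0x7E7, attempt)
        )
        traj = _simulate_once(spec, config, ss, rng if attempt == 0 else None)
        if _trajectory_valid(traj):
            return traj
    raise InitializationError(
        f"no constraint-satisfying trajectory in {max_trial_retries} attempts"
    )


def _trajectory_valid(traj: Trajectory) -> bool:
    """Post-hoc scan: distance floor and pairwise non-overlap on all frames."""
    cfg = traj.config
    if traj.wolf_sheep_distances().min() < cfg.wolf_sheep_min_dist - 1e-12:
        return False
    for i in range(traj.n_dots):
        for j in range(i + 1, traj.n_dots):
            if traj.pair_distances(i, j).min() < cfg.dot_diameter - 1e-12:
                return False
    return True


def _simulate_once(
    spec: TrialSpec,
    config: SimConfig,
    ss: np.random.SeedSequence,
    rng: np.random.Generator | None,
) -> Trajectory:
    if spec.chase_present:
        roles: tuple[str, ...] = ("sheep", "distractor", "distractor", "wolf")
    else:
        roles = ("invisible_sheep", "distractor", "distractor", "distractor", "wolf")
    n_dots = len(roles)
    wolf = roles.index("wolf")
    sheep = 0  # target first by construction

    children = ss.spawn(n_dots + 1)
    init_rng = rng if rng is not None else np.random.default_rng(children[0])
    dot_rngs = [np.random.default_rng(c) for c in children[1:]]

    F = config.n_frames
    K = config.update_interval_frames
    onset = config.chase_onset_frames
    step = config.frame_step
    half_w = config.arena_width / 2.0 - config.dot_diameter / 2.0
    half_h = config.arena_height / 2.0 - config.dot_diameter / 2.0

    positions = np.empty((F, n_dots, 2))
    headings = np.empty((F, n_dots))
    update_log = np.zeros((F, n_dots), dtype=bool)
    override_log = np.zeros((F, n_dots), dtype=bool)
    reflect_log = np.zeros((F, n_dots), dtype=bool)

    init = _initial_positions(n_dots, wolf, sheep, config, init_rng)
    phases = [int(dot_rngs[d].integers(0, K)) for d in range(n_dots)]
    cur_pos: list[tuple[float, float]] = list(init)
    cur_head = [float(dot_rngs[d].uniform(0.0, 360.0)) for d in range(n_dots)]
    positions[0] = np.asarray(cur_pos)
    headings[0] = np.asarray(cur_head)

    order = list(range(n_dots))  # sheep first, wolf last, by construction
    for t in range(1, F):
        for d in order:
            drng = dot_rngs[d]
            prev_h = cur_head[d]
            is_update = (t % K) == phases[d]
            if is_update:
                if d == wolf and t >= onset:
                    proposed = sample_wolf_heading(
                        cur_pos[d], cur_pos[sheep], spec.subtlety, drng
                    )
                else:
                    proposed = sample_random_heading(
                        prev_h, config.random_window, drng
                    )
            else:
                proposed = prev_h
            others = [cur_pos[e] for e in range(n_dots) if e != d]
            sheep_pos = cur_pos[sheep] if d == wolf else None
            h, override = _resolve_heading(
                proposed, prev_h, cur_pos[d], d == wolf, sheep_pos,
                others, config, half_w, half_h, drng,
            )
            nx, ny, h_after, hit = _step_position(
                cur_pos[d][0], cur_pos[d][1], h, step,
                half_w, half_h, config.boundary_mode, drng,
            )
            cur_pos[d] = (nx, ny)
            cur_head[d] = h_after
            update_log[t, d] = is_update
            override_log[t, d] = override
            reflect_log[t, d] = hit
        positions[t] = np.asarray(cur_pos)
        headings[t] = np.asarray(cur_head)

    return Trajectory(
        positions=positions,
        headings=headings,
        roles=roles,
        update_log=update_log,
        override_log=override_log,
        reflect_log=reflect_log,
        spec=spec,
        config=config,
    )
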