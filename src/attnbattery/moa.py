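"""Multiple Object Avoidance (MOA) trial and session engine.

A pointer-controlled user disc shares an 800x800 px playfield with moving
hazard discs.  Hazards appear unfilled (non-collidable) for a short grace
period, then fill in; a new hazard is added at every spawn interval.  The
trial ends when a filled hazard touches the user disc, and the survival
time in seconds is the score.  A session is a fixed number of practice plus
recorded trials; the session score is the mean survival time over the
recorded trials only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from attnbattery.kinematics import (
    MovingDisc,
    PlayfieldBounds,
    Vector2D,
    collide_pair,
    overlapping,
    reflect_wall,
)
from attnbattery.seeding import TASK_CODES, derive_seed, rng_from_seed

__all__ = [
    "MOAConfig",
    "HazardState",
    "MOAEngineState",
    "TrialRecord",
    "MOASessionResult",
    "init_trial",
    "step",
    "run_trial",
    "run_session",
]

# Rejection-sampling budget for non-overlapping placement of one hazard.
_MAX_PLACEMENT_ATTEMPTS = 10_000
# Tolerance for comparing the tick-quantized clock against event times.
_CLOCK_EPS = 1e-9


@dataclass(frozen=True)
class MOAConfig:
    """Task parameters; defaults reproduce the published configuration."""

    window: PlayfieldBounds = PlayfieldBounds(800.0, 800.0)
    disc_diameter: float = 40.0
    n_initial_hazards: int = 3
    spawn_interval: float = 10.0
    grace_duration: float = 1.0
    speed_min: float = 0.0
    speed_max: float = 680.0
    tick: float = 1.0 / 85.0
    n_practice_trials: int = 2
    n_recorded_trials: int = 8
    max_trial_duration: float = 300.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.disc_diameter <= 0:
            raise ValueError("disc_diameter must be positive")
        if self.speed_min > self.speed_max or self.speed_min < 0:
            raise ValueError("require 0 <= speed_min <= speed_max")
        if self.spawn_interval <= 0:
            raise ValueError("spawn_interval must be positive")
        if self.grace_duration < 0:
            raise ValueError("grace_duration must be nonnegative")
        if self.tick <= 0:
            raise ValueError("tick must be positive")
        if self.max_trial_duration <= 0:
            raise ValueError("max_trial_duration must be positive")
        for name in ("n_initial_hazards", "n_practice_trials", "n_recorded_trials"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def radius(self) -> float:
        return self.disc_diameter / 2.0


@dataclass
class HazardState:
    """One hazard disc plus its grace-period bookkeeping."""

    disc: MovingDisc
    filled: bool
    activation_time: float


@dataclass
class MOAEngineState:
    """Full mutable state of one MOA trial."""

    user: MovingDisc
    hazards: list[HazardState]
    next_spawn_time: float
    tick_index: int = 0
    clock: float = 0.0
    terminated: bool = False
    censored: bool = False
    survival_time: float | None = None
    rng: np.random.Generator = field(default_factory=np.random.default_rng, repr=False)


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of a single trial."""

    trial_index: int
    practice: bool
    seed: int
    survival_time: float
    censored: bool


@dataclass(frozen=True)
class MOASessionResult:
    """All trial records of one session plus the session score."""

    records: list[TrialRecord]
    moa_score: float


def _clamp(v: float, lo: float, hi: float) -> float:
    return lo if v < lo else hi if v > hi else v


def _place_hazard(
    rng: np.random.Generator,
    config: MOAConfig,
    obstacles: list[MovingDisc],
    activation_time: float,
) -> HazardState:
    """Uniform random placement not overlapping any existing disc.

    Draw order per attempt is (x, y); direction and speed are drawn once
    after a position is accepted, keeping the stream layout stable.
    """
    r = config.radius
    w, h = config.window.width, config.window.height
    if w < 2 * r or h < 2 * r:
        raise ValueError("window too small for disc diameter")
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        x = rng.uniform(r, w - r)
        y = rng.uniform(r, h - r)
        candidate = MovingDisc(Vector2D(x, y), Vector2D(0.0, 0.0), r)
        if any(overlapping(candidate, d) for d in obstacles):
            continue
        angle = rng.uniform(0.0, 2.0 * math.pi)
        speed = rng.uniform(config.speed_min, config.speed_max)
        velocity = Vector2D(speed * math.cos(angle), speed * math.sin(angle))
        return HazardState(
            disc=replace(candidate, velocity=velocity),
            filled=False,
            activation_time=activation_time,
        )
    raise ValueError(
        "could not place a hazard without overlap after "
        f"{_MAX_PLACEMENT_ATTEMPTS} attempts; window too crowded"
    )


def init_trial(config: MOAConfig, trial_seed: int) -> MOAEngineState:
    """Set up a trial: user disc at the window center, unfilled hazards placed
    uniformly at random with mutually non-overlapping positions, random
    headings on [0, 360) degrees, and speeds uniform on
    [speed_min, speed_max]."""
    rng = rng_from_seed(trial_seed)
    r = config.radius
    user = MovingDisc(
        Vector2D(config.window.width / 2.0, config.window.height / 2.0),
        Vector2D(0.0, 0.0),
        r,
    )
    hazards: list[HazardState] = []
    for _ in range(config.n_initial_hazards):
        obstacles = [user] + [hz.disc for hz in hazards]
        hazards.append(_place_hazard(rng, config, obstacles, config.grace_duration))
    return MOAEngineState(
        user=user,
        hazards=hazards,
        next_spawn_time=config.spawn_interval,
        rng=rng,
    )


def _advance_hazards(state: MOAEngineState, config: MOAConfig) -> None:
    """One tick of hazard motion with wall and hazard-hazard collisions.

    Substeps when the fastest hazard would move more than half a radius per
    substep (tunnelling guard); the default configuration (680 px/s at 85 Hz
    moves 8 px against a 20 px radius) never substeps.
    """
    hazards = state.hazards
    if not hazards:
        return
    max_speed = max(hz.disc.speed for hz in hazards)
    n_sub = max(1, math.ceil(max_speed * config.tick / (config.radius / 2.0)))
    dt = config.tick / n_sub
    for _ in range(n_sub):
        for hz in hazards:
            d = hz.disc
            c = d.center
            v = d.velocity
            hz.disc = replace(d, center=Vector2D(c.x + v.x * dt, c.y + v.y * dt))
        for hz in hazards:
            hz.disc = reflect_wall(hz.disc, config.window)
        for i in range(len(hazards)):
            for j in range(i + 1, len(hazards)):
                a, b = collide_pair(hazards[i].disc, hazards[j].disc)
                hazards[i].disc = a
                hazards[j].disc = b


def step(state: MOAEngineState, pointer: Vector2D, config: MOAConfig) -> MOAEngineState:
    """Advance the trial by one tick.

    The user disc center teleports to the pointer sample clamped into the
    playfield (the engine imposes no pointer-speed limit; speed limits live
    in agent specs).  Hazards move, bounce, fill in after their grace
    period, and a new one spawns at each spawn-interval multiple.  A filled
    hazard overlapping the user terminates the trial with the current clock
    as the survival time; reaching the duration cap censors the trial.
    """
    if state.terminated:
        raise ValueError("cannot step a terminated trial")

    r = config.radius
    px = _clamp(pointer.x, r, config.window.width - r)
    py = _clamp(pointer.y, r, config.window.height - r)
    state.user = replace(state.user, center=Vector2D(px, py))

    state.tick_index += 1
    clock = state.tick_index * config.tick
    state.clock = clock

    _advance_hazards(state, config)

    for hz in state.hazards:
        if not hz.filled and clock >= hz.activation_time - _CLOCK_EPS:
            hz.filled = True

    while clock >= state.next_spawn_time - _CLOCK_EPS:
        obstacles = [state.user] + [hz.disc for hz in state.hazards]
        state.hazards.append(
            _place_hazard(
                state.rng,
                config,
                obstacles,
                state.next_spawn_time + config.grace_duration,
            )
        )
        state.next_spawn_time += config.spawn_interval

    user = state.user
    for hz in state.hazards:
        if hz.filled and overlapping(hz.disc, user):
            state.terminated = True
            state.survival_time = clock
            return state

    if clock >= config.max_trial_duration - _CLOCK_EPS:
        state.terminated = True
        state.censored = True
        state.survival_time = config.max_trial_duration
    return state


def run_trial(
    config: MOAConfig,
    controller,
    trial_seed: int,
    *,
    trial_index: int = 0,
    practice: bool = False,
) -> TrialRecord:
    """Run one trial to termination with pointer samples from ``controller``.

    ``controller`` is any object with ``reset(trial_seed)`` and
    ``pointer(state, config) -> Vector2D`` (see :mod:`attnbattery.agents`).
    """
    state = init_trial(config, trial_seed)
    controller.reset(trial_seed)
    while not state.terminated:
        target = controller.pointer(state, config)
        step(state, target, config)
    assert state.survival_time is not None
    return TrialRecord(
        trial_index=trial_index,
        practice=practice,
        seed=trial_seed,
        survival_time=state.survival_time,
        censored=state.censored,
    )


def run_session(config: MOAConfig, controller) -> MOASessionResult:
    """Run practice + recorded trials with per-trial seeds derived from the
    config's master seed; the session score averages recorded trials only."""
    records: list[TrialRecord] = []
    n_total = config.n_practice_trials + config.n_recorded_trials
    for i in range(n_total):
        trial_seed = derive_seed(config.master_seed, TASK_CODES["MOA"], i)
        records.append(
            run_trial(
                config,
                controller,
                trial_seed,
                trial_index=i,
                practice=i < config.n_practice_trials,
            )
        )
    recorded = [rec.survival_time for rec in records if not rec.practice]
    if not recorded:
        raise ValueError("session has no recorded trials to score")
    return MOASessionResult(records=records, moa_score=float(np.mean(recorded)))
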