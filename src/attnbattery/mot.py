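"""Multiple Object Tracking (MOT) trial engine.

Ten identical squares appear at random positions; a random subset flash as
targets, then all squares drift along fixed headings drawn from a finite
direction set at speeds drawn from a finite speed set, mirror-reflecting
off window edges and overlapping freely.  After the movement phase the
observer selects the squares believed to be the targets; accuracy is the
fraction of true targets selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from attnbattery.kinematics import PlayfieldBounds, Vector2D
from attnbattery.seeding import TASK_CODES, derive_seed, rng_from_seed

__all__ = [
    "MOTConfig",
    "MOTTrialState",
    "MOTTrialResult",
    "MOTSessionResult",
    "init_mot_trial",
    "step_mot",
    "score_selection",
    "run_mot_trial",
    "run_mot_session",
]

_CLOCK_EPS = 1e-9

DEFAULT_DIRECTIONS_DEG = (18, 45, 72, 108, 135, 162, 198, 225, 252, 288, 315, 342)
DEFAULT_SPEEDS = (60.0, 134.0, 180.0)


@dataclass(frozen=True)
class MOTConfig:
    """Task parameters; defaults reproduce the published configuration."""

    window: PlayfieldBounds = PlayfieldBounds(1014.0, 758.0)
    square_side: float = 30.0
    n_squares: int = 10
    n_targets: int = 5
    direction_set: tuple[float, ...] = DEFAULT_DIRECTIONS_DEG
    speed_set: tuple[float, ...] = DEFAULT_SPEEDS
    flash_duration: float = 2.5
    move_duration: float = 8.0
    n_trials: int = 30
    tick: float = 1.0 / 85.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets > self.n_squares or self.n_targets < 0:
            raise ValueError("require 0 <= n_targets <= n_squares")
        if not self.direction_set:
            raise ValueError("direction_set must be non-empty")
        if any(s <= 0 for s in self.speed_set):
            raise ValueError("speeds must be positive")
        if self.tick <= 0 or self.move_duration <= 0:
            raise ValueError("tick and move_duration must be positive")
        if self.square_side <= 0:
            raise ValueError("square_side must be positive")

    @property
    def margin(self) -> float:
        """Half-side containment margin for square centers."""
        return self.square_side / 2.0


@dataclass
class MOTTrialState:
    """Mutable state of one trial; squares are stored as parallel arrays."""

    xs: np.ndarray
    ys: np.ndarray
    directions_deg: np.ndarray
    speeds: np.ndarray
    target_indices: frozenset[int]
    phase: str = "flash"  # flash -> moving -> select -> done
    clock: float = 0.0
    tick_index: int = 0

    @property
    def squares(self) -> list[tuple[Vector2D, float, float]]:
        """(center, direction in degrees, speed) per square."""
        return [
            (Vector2D(float(x), float(y)), float(d), float(s))
            for x, y, d, s in zip(self.xs, self.ys, self.directions_deg, self.speeds)
        ]


@dataclass(frozen=True)
class MOTTrialResult:
    n_correct: int
    accuracy: float


@dataclass(frozen=True)
class MOTSessionResult:
    trials: list[MOTTrialResult]
    mean_accuracy: float


def init_mot_trial(config: MOTConfig, trial_seed: int) -> MOTTrialState:
    """Place squares uniformly at random fully inside the window (overlap
    permitted), pick targets without replacement, and assign each square a
    direction and speed uniformly from the configured finite sets.

    Draw order: x positions, y positions, directions, speeds, targets.
    """
    rng = rng_from_seed(trial_seed)
    m = config.margin
    w, h = config.window.width, config.window.height
    n = config.n_squares
    xs = rng.uniform(m, w - m, size=n)
    ys = rng.uniform(m, h - m, size=n)
    directions = rng.choice(np.asarray(config.direction_set, dtype=float), size=n)
    speeds = rng.choice(np.asarray(config.speed_set, dtype=float), size=n)
    targets = frozenset(int(i) for i in rng.choice(n, size=config.n_targets, replace=False))
    return MOTTrialState(
        xs=xs,
        ys=ys,
        directions_deg=directions,
        speeds=speeds,
        target_indices=targets,
    )


def begin_movement(state: MOTTrialState) -> MOTTrialState:
    """End the flash phase (a headless no-op) and start the movement phase."""
    if state.phase != "flash":
        raise ValueError(f"cannot begin movement from phase {state.phase!r}")
    state.phase = "moving"
    return state


def step_mot(state: MOTTrialState, config: MOTConfig) -> MOTTrialState:
    """Advance all squares one tick along their headings.

    Squares crossing a window edge reflect by an axis-aligned mirror of the
    heading (headings may leave the initial direction set mid-trial; set
    membership applies at assignment only).  Squares never inter-collide.
    Speed assignments never change.  The phase flips to ``select`` once the
    movement duration has elapsed.
    """
    if state.phase != "moving":
        raise ValueError(f"cannot step in phase {state.phase!r}")

    theta = np.deg2rad(state.directions_deg)
    state.xs = state.xs + state.speeds * np.cos(theta) * config.tick
    state.ys = state.ys + state.speeds * np.sin(theta) * config.tick

    m = config.margin
    w, h = config.window.width, config.window.height
    # Horizontal mirror: theta -> 180 - theta; vertical mirror: theta -> -theta.
    lo_x = state.xs < m
    hi_x = state.xs > w - m
    if lo_x.any() or hi_x.any():
        state.xs = np.where(lo_x, 2 * m - state.xs, state.xs)
        state.xs = np.where(hi_x, 2 * (w - m) - state.xs, state.xs)
        flip = lo_x | hi_x
        state.directions_deg = np.where(
            flip, np.mod(180.0 - state.directions_deg, 360.0), state.directions_deg
        )
    lo_y = state.ys < m
    hi_y = state.ys > h - m
    if lo_y.any() or hi_y.any():
        state.ys = np.where(lo_y, 2 * m - state.ys, state.ys)
        state.ys = np.where(hi_y, 2 * (h - m) - state.ys, state.ys)
        flip = lo_y | hi_y
        state.directions_deg = np.where(
            flip, np.mod(-state.directions_deg, 360.0), state.directions_deg
        )

    state.tick_index += 1
    state.clock = state.tick_index * config.tick
    if state.clock >= config.move_duration - _CLOCK_EPS:
        state.phase = "select"
    return state


def score_selection(
    state: MOTTrialState, selection: set[int], config: MOTConfig
) -> MOTTrialResult:
    """Count selected true targets; accuracy = n_correct / n_targets."""
    if state.phase != "select":
        raise ValueError(f"cannot score in phase {state.phase!r}")
    if len(selection) != config.n_targets:
        raise ValueError(
            f"selection must contain exactly {config.n_targets} squares, "
            f"got {len(selection)}"
        )
    if not all(0 <= int(i) < config.n_squares for i in selection):
        raise ValueError("selection contains an invalid square id")
    n_correct = len(set(int(i) for i in selection) & state.target_indices)
    return MOTTrialResult(n_correct=n_correct, accuracy=n_correct / config.n_targets)


def run_mot_trial(config: MOTConfig, observer, trial_seed: int) -> MOTTrialResult:
    """One full trial: init, movement phase, observer selection, scoring.

    ``observer`` is any object with ``reset(trial_seed)`` and
    ``select(state, config) -> set of square ids``.
    """
    state = init_mot_trial(config, trial_seed)
    begin_movement(state)
    while state.phase == "moving":
        step_mot(state, config)
    observer.reset(trial_seed)
    selection = observer.select(state, config)
    return score_selection(state, selection, config)


def run_mot_session(config: MOTConfig, observer) -> MOTSessionResult:
    """Run the configured number of trials with derived per-trial seeds."""
    trials = [
        run_mot_trial(config, observer, derive_seed(config.master_seed, TASK_CODES["MOT"], i))
        for i in range(config.n_trials)
    ]
    mean_accuracy = float(np.mean([t.accuracy for t in trials])) if trials else math.nan
    return MOTSessionResult(trials=trials, mean_accuracy=mean_accuracy)
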