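"""Parametric synthetic agents standing in for human participants.

Controllers drive the avoidance-task pointer (stationary, random walk, and
a greedy time-to-collision avoider with reaction latency, a pointer-speed
cap, and motor noise).  Observers answer tracking trials with a capacity-k
policy: k targets tracked perfectly, the rest guessed uniformly.  The
cohort generator draws per-participant skill parameters from per-group
distributions and runs full sessions of all three tasks, producing a tidy
score table with designed group effects.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from attnbattery.dsst import generate_form, score_dsst, simulate_responder
from attnbattery.kinematics import Vector2D
from attnbattery.moa import MOAConfig, MOAEngineState, run_session
from attnbattery.mot import MOTConfig, MOTTrialState, run_mot_session
from attnbattery.seeding import TASK_CODES, derive_seed

__all__ = [
    "ControllerSpec",
    "ObserverSpec",
    "GroupSpec",
    "CohortSpec",
    "StationaryController",
    "RandomWalkController",
    "GreedyAvoidController",
    "CapacityObserver",
    "make_controller",
    "greedy_avoid_pointer",
    "capacity_k_select",
    "simulate_cohort",
]

CONTROLLER_KINDS = ("stationary", "random_walk", "greedy_avoid")


@dataclass(frozen=True)
class ControllerSpec:
    """Parameters of a synthetic pointer controller."""

    kind: str = "greedy_avoid"
    reaction_latency: float = 0.0
    max_pointer_speed: float = 800.0
    motor_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CONTROLLER_KINDS:
            raise ValueError(f"unknown controller kind {self.kind!r}")
        if self.reaction_latency < 0:
            raise ValueError("reaction_latency must be nonnegative")
        if self.max_pointer_speed <= 0:
            raise ValueError("max_pointer_speed must be positive")
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be nonnegative")


@dataclass(frozen=True)
class ObserverSpec:
    """Capacity-limited tracking observer: tracks ``capacity_k`` targets
    perfectly and guesses the remaining selections uniformly."""

    capacity_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capacity_k < 0:
            raise ValueError("capacity_k must be nonnegative")


def _agent_rng(spec_seed: int, trial_seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([TASK_CODES["AGENT"], int(spec_seed), int(trial_seed)])
    )


class StationaryController:
    """Never moves: the pointer stays wherever the user disc is."""

    def __init__(self, spec: ControllerSpec):
        self.spec = spec

    def reset(self, trial_seed: int) -> None:
        pass

    def pointer(self, state: MOAEngineState, config: MOAConfig) -> Vector2D:
        return state.user.center


class RandomWalkController:
    """Moves the pointer a fixed-magnitude step in a uniformly random
    direction each tick (speed-capped drunkard's walk)."""

    def __init__(self, spec: ControllerSpec):
        self.spec = spec
        self._rng = np.random.default_rng(spec.seed)

    def reset(self, trial_seed: int) -> None:
        self._rng = _agent_rng(self.spec.seed, trial_seed)

    def pointer(self, state: MOAEngineState, config: MOAConfig) -> Vector2D:
        angle = self._rng.uniform(0.0, 2.0 * math.pi)
        step_len = self.spec.max_pointer_speed * config.tick
        dx = step_len * math.cos(angle)
        dy = step_len * math.sin(angle)
        if self.spec.motor_noise_sd > 0:
            dx += self._rng.normal(0.0, self.spec.motor_noise_sd)
            dy += self._rng.normal(0.0, self.spec.motor_noise_sd)
        c = state.user.center
        return Vector2D(c.x + dx, c.y + dy)


def _time_to_collision(
    user_center: Vector2D, hazard_center: Vector2D, hazard_velocity: Vector2D, radius_sum: float
) -> float:
    """Projected time until the center gap closes to the radius sum.

    The closing speed is the projection of the relative velocity onto the
    center line; a receding (or stationary-gap) hazard has infinite TTC.
    """
    rel = hazard_center - user_center
    dist = rel.norm()
    if dist <= radius_sum:
        return 0.0
    closing = -(rel.dot(hazard_velocity)) / dist
    if closing <= 0.0:
        return math.inf
    return (dist - radius_sum) / closing


def greedy_avoid_pointer(
    state: MOAEngineState,
    spec: ControllerSpec,
    config: MOAConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    snapshot=None,
) -> Vector2D:
    """One greedy-avoidance pointer proposal.

    Finds the hazard with the smallest time-to-collision among those that
    are filled (or will have filled within the agent's reaction latency)
    and proposes a displacement directly away from it, capped at
    ``max_pointer_speed * tick`` and perturbed by isotropic Gaussian motor
    noise.  With no approaching threat the pointer holds position.

    ``snapshot`` optionally supplies the delayed percept used by
    :class:`GreedyAvoidController` — a ``(clock, user_center, hazards)``
    tuple with hazards as ``(center, velocity, filled, activation_time)``.
    """
    if snapshot is None:
        clock = state.clock
        seen_user = state.user.center
        seen_hazards = [
            (hz.disc.center, hz.disc.velocity, hz.filled, hz.activation_time)
            for hz in state.hazards
        ]
    else:
        clock, seen_user, seen_hazards = snapshot

    radius_sum = config.radius * 2.0
    best_ttc = math.inf
    threat_center: Optional[Vector2D] = None
    for center, velocity, filled, activation_time in seen_hazards:
        if not filled and activation_time - clock >= spec.reaction_latency:
            continue  # still safely in grace by the time the action lands
        ttc = _time_to_collision(seen_user, center, velocity, radius_sum)
        if ttc < best_ttc:
            best_ttc = ttc
            threat_center = center

    current = state.user.center
    if threat_center is None or math.isinf(best_ttc):
        return current

    away = seen_user - threat_center
    away_norm = away.norm()
    step_len = spec.max_pointer_speed * config.tick
    if away_norm == 0.0:
        dx, dy = step_len, 0.0  # coincident centers: flee along +x
    else:
        dx = away.x / away_norm * step_len
        dy = away.y / away_norm * step_len
    if spec.motor_noise_sd > 0 and rng is not None:
        dx += rng.normal(0.0, spec.motor_noise_sd)
        dy += rng.normal(0.0, spec.motor_noise_sd)
    return Vector2D(current.x + dx, current.y + dy)


class GreedyAvoidController:
    """TTC-greedy avoider with reaction latency, speed cap, and motor noise.

    Latency is implemented as acting on a percept snapshot delayed by a
    whole number of ticks (``round(latency / tick)``); until enough history
    exists the oldest available snapshot is used.
    """

    def __init__(self, spec: ControllerSpec):
        self.spec = spec
        self._rng = np.random.default_rng(spec.seed)
        self._history: deque = deque()

    def reset(self, trial_seed: int) -> None:
        self._rng = _agent_rng(self.spec.seed, trial_seed)
        self._history = deque()

    def pointer(self, state: MOAEngineState, config: MOAConfig) -> Vector2D:
        delay_ticks = round(self.spec.reaction_latency / config.tick)
        snap = (
            state.clock,
            state.user.center,
            [
                (hz.disc.center, hz.disc.velocity, hz.filled, hz.activation_time)
                for hz in state.hazards
            ],
        )
        self._history.append(snap)
        while len(self._history) > delay_ticks + 1:
            self._history.popleft()
        return greedy_avoid_pointer(
            state, self.spec, config, self._rng, snapshot=self._history[0]
        )


def make_controller(spec: ControllerSpec):
    """Instantiate the controller class named by ``spec.kind``."""
    cls = {
        "stationary": StationaryController,
        "random_walk": RandomWalkController,
        "greedy_avoid": GreedyAvoidController,
    }[spec.kind]
    return cls(spec)


def capacity_k_select(
    state: MOTTrialState,
    spec: ObserverSpec,
    config: MOTConfig,
    rng: Optional[np.random.Generator] = None,
) -> set[int]:
    """Capacity-k selection policy.

    Returns ``min(capacity_k, n_targets)`` true targets chosen uniformly
    among the targets, topped up with a uniform random draw from the
    remaining (unidentified) squares to exactly ``n_targets`` selections.
    """
    if state.phase != "select":
        raise ValueError(f"cannot select in phase {state.phase!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    targets = sorted(state.target_indices)
    k = min(spec.capacity_k, config.n_targets)
    tracked = set(
        int(i) for i in rng.choice(np.asarray(targets), size=k, replace=False)
    ) if k else set()
    remaining = sorted(set(range(config.n_squares)) - tracked)
    n_fill = config.n_targets - k
    fill = set(
        int(i) for i in rng.choice(np.asarray(remaining), size=n_fill, replace=False)
    ) if n_fill else set()
    return tracked | fill


class CapacityObserver:
    """Observer protocol wrapper around :func:`capacity_k_select`."""

    def __init__(self, spec: ObserverSpec):
        self.spec = spec
        self._rng = np.random.default_rng(spec.seed)

    def reset(self, trial_seed: int) -> None:
        self._rng = _agent_rng(self.spec.seed, trial_seed)

    def select(self, state: MOTTrialState, config: MOTConfig) -> set[int]:
        return capacity_k_select(state, self.spec, config, self._rng)


@dataclass(frozen=True)
class GroupSpec:
    """Per-group skill-parameter distributions for the cohort generator."""

    n: int
    latency_mean: float = 0.15
    latency_sd: float = 0.05
    pointer_speed_mean: float = 700.0
    pointer_speed_sd: float = 100.0
    motor_noise_sd: float = 2.0
    capacity_mean: float = 3.0
    capacity_sd: float = 1.0
    dsst_rate_mean: float = 0.8
    dsst_rate_sd: float = 0.15
    dsst_error_prob: float = 0.05
    age_mean: float = 24.0
    age_sd: float = 4.5

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for name in (
            "latency_sd",
            "pointer_speed_sd",
            "capacity_sd",
            "dsst_rate_sd",
            "age_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.dsst_error_prob <= 1.0:
            raise ValueError("dsst_error_prob must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group synthetic cohort with engine configs and a master seed."""

    group_a: GroupSpec
    group_b: GroupSpec
    label_a: str = "A"
    label_b: str = "B"
    moa_config: MOAConfig = MOAConfig()
    mot_config: MOTConfig = MOTConfig()
    dsst_duration: float = 60.0
    master_seed: int = 0


def _draw_participant_params(rng: np.random.Generator, g: GroupSpec, mot: MOTConfig):
    latency = max(0.0, float(rng.normal(g.latency_mean, g.latency_sd)))
    pointer_speed = max(50.0, float(rng.normal(g.pointer_speed_mean, g.pointer_speed_sd)))
    capacity = int(np.clip(round(rng.normal(g.capacity_mean, g.capacity_sd)), 0, mot.n_targets))
    dsst_rate = max(0.05, float(rng.normal(g.dsst_rate_mean, g.dsst_rate_sd)))
    age = float(rng.normal(g.age_mean, g.age_sd))
    return latency, pointer_speed, capacity, dsst_rate, age


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate every participant's full battery and return the score table.

    Each participant's skill parameters are drawn from their group's
    distributions; their scores then come from actually running a full MOA
    session, a full MOT session, and a DSST simulation — scores are never
    sampled directly.  Fully reproducible from ``master_seed``.
    """
    rows = []
    idx = 0
    for label, group in ((spec.label_a, spec.group_a), (spec.label_b, spec.group_b)):
        for _ in range(group.n):
            pseed = derive_seed(spec.master_seed, TASK_CODES["COHORT"], idx)
            rng = np.random.default_rng(pseed)
            latency, pointer_speed, capacity, dsst_rate, age = _draw_participant_params(
                rng, group, spec.mot_config
            )

            moa_cfg = replace(spec.moa_config, master_seed=derive_seed(pseed, 1, 0))
            controller = GreedyAvoidController(
                ControllerSpec(
                    kind="greedy_avoid",
                    reaction_latency=latency,
                    max_pointer_speed=pointer_speed,
                    motor_noise_sd=group.motor_noise_sd,
                    seed=derive_seed(pseed, 1, 1),
                )
            )
            moa_score = run_session(moa_cfg, controller).moa_score

            mot_cfg = replace(spec.mot_config, master_seed=derive_seed(pseed, 2, 0))
            observer = CapacityObserver(
                ObserverSpec(capacity_k=capacity, seed=derive_seed(pseed, 2, 1))
            )
            mot_accuracy = run_mot_session(mot_cfg, observer).mean_accuracy

            form = generate_form(derive_seed(pseed, 3, 0))
            response = simulate_responder(
                form,
                rate=dsst_rate,
                error_prob=group.dsst_error_prob,
                duration=spec.dsst_duration,
                seed=derive_seed(pseed, 3, 1),
            )
            dsst_score = score_dsst(form, response).n_correct

            rows.append(
                {
                    "participant_id": idx,
                    "group": label,
                    "age_years": age,
                    "moa_score_s": moa_score,
                    "mot_mean_accuracy": mot_accuracy,
                    "dsst_score": dsst_score,
                }
            )
            idx += 1
    return pd.DataFrame(rows)
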