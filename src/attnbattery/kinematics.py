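"""Continuous 2D disc motion, wall reflection, and pair-collision resolution.

Coordinate convention: origin at the top-left corner of the playfield,
x increasing rightwards, y increasing downwards; positions are continuous
floats at disc centers and the window is the half-open box [0, W) x [0, H).

Integration is explicit fixed-timestep Euler.  Motion between collision
events is piecewise linear, so Euler is exact between events; engines check
for wall/pair contact after every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "Vector2D",
    "MovingDisc",
    "PlayfieldBounds",
    "advance",
    "reflect_wall",
    "collide_pair",
    "overlapping",
]


@dataclass(frozen=True)
class Vector2D:
    """A point or displacement in playfield pixels."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite vector components ({self.x}, {self.y})")

    def __add__(self, other: "Vector2D") -> "Vector2D":
        return Vector2D(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "Vector2D") -> "Vector2D":
        return Vector2D(self.x - other.x, self.y - other.y)

    def scaled(self, k: float) -> "Vector2D":
        return Vector2D(self.x * k, self.y * k)

    def dot(self, other: "Vector2D") -> float:
        return self.x * other.x + self.y * other.y

    def norm(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class MovingDisc:
    """A circular entity with a center, a velocity, and a radius (all px)."""

    center: Vector2D
    velocity: Vector2D
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @property
    def speed(self) -> float:
        return self.velocity.norm()


@dataclass(frozen=True)
class PlayfieldBounds:
    """Axis-aligned rectangular playfield of width x height pixels."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"playfield dimensions must be positive, got {self.width}x{self.height}"
            )


def advance(disc: MovingDisc, dt: float) -> MovingDisc:
    """Move ``disc`` along its straight-line trajectory for ``dt`` seconds."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return replace(disc, center=disc.center + disc.velocity.scaled(dt))


def reflect_wall(disc: MovingDisc, bounds: PlayfieldBounds) -> MovingDisc:
    """Bounce ``disc`` off any playfield edge it has reached or crossed.

    For each violated edge the velocity component normal to that edge is
    negated and the center is clamped so the disc lies fully inside the
    playfield.  Speed is preserved exactly (components are only negated).
    A fully interior disc is returned unchanged.
    """
    r = disc.radius
    x, y = disc.center.x, disc.center.y
    vx, vy = disc.velocity.x, disc.velocity.y
    if x < r:
        x, vx = r, -vx
    elif x > bounds.width - r:
        x, vx = bounds.width - r, -vx
    if y < r:
        y, vy = r, -vy
    elif y > bounds.height - r:
        y, vy = bounds.height - r, -vy
    if x == disc.center.x and y == disc.center.y and vx == disc.velocity.x and vy == disc.velocity.y:
        return disc
    return replace(disc, center=Vector2D(x, y), velocity=Vector2D(vx, vy))


def overlapping(a: MovingDisc, b: MovingDisc) -> bool:
    """True iff the discs' interiors intersect (strict; tangency is not contact)."""
    return (a.center - b.center).norm() < a.radius + b.radius


def _approaching(a: MovingDisc, b: MovingDisc) -> bool:
    rel_pos = b.center - a.center
    rel_vel = b.velocity - a.velocity
    return rel_pos.dot(rel_vel) < 0


def collide_pair(a: MovingDisc, b: MovingDisc) -> tuple[MovingDisc, MovingDisc]:
    """Resolve an overlapping, approaching disc pair.

    Each disc's velocity is specularly reflected about the collision normal
    (the center-to-center unit vector), preserving each disc's own speed —
    each entity keeps its randomized speed for the whole trial.  Centers are
    pushed apart along the normal to exact tangency.  When the pair is not
    overlapping, or overlapping but receding, the inputs are returned
    unchanged (no re-collision on the way out).

    Coincident centers (measure-zero degenerate case) separate along +x.
    """
    if not overlapping(a, b):
        return a, b
    delta = b.center - a.center
    dist = delta.norm()
    if dist == 0.0:
        nx, ny = 1.0, 0.0  # degenerate: coincident centers always resolve
    elif _approaching(a, b):
        nx, ny = delta.x / dist, delta.y / dist
    else:
        return a, b

    def _reflect(v: Vector2D) -> Vector2D:
        k = 2.0 * (v.x * nx + v.y * ny)
        return Vector2D(v.x - k * nx, v.y - k * ny)

    # Push each center half the penetration depth outward along the normal.
    push = 0.5 * (a.radius + b.radius - dist)
    new_a = replace(
        a,
        center=Vector2D(a.center.x - push * nx, a.center.y - push * ny),
        velocity=_reflect(a.velocity),
    )
    new_b = replace(
        b,
        center=Vector2D(b.center.x + push * nx, b.center.y + push * ny),
        velocity=_reflect(b.velocity),
    )
    return new_a, new_b
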