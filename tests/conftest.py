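import numpy as np
import pytest

from attnbattery.kinematics import MovingDisc, PlayfieldBounds, Vector2D
from attnbattery.moa import MOAConfig, MOAEngineState


@pytest.fixture
def bounds():
    return PlayfieldBounds(800.0, 800.0)


@pytest.fixture
def default_moa():
    return MOAConfig()


def make_disc(x, y, vx, vy, r=20.0):
    return MovingDisc(Vector2D(x, y), Vector2D(vx, vy), r)


def single_hazard_state(config: MOAConfig, d: float, v: float) -> MOAEngineState:
    """User at window center, one filled hazard d px to the right aimed
    straight at the user at speed v; trial-clock bookkeeping fresh."""
    r = config.radius
    user = make_disc(config.window.width / 2, config.window.height / 2, 0, 0, r)
    hazard = make_disc(user.center.x + d, user.center.y, -v, 0.0, r)
    from attnbattery.moa import HazardState

    return MOAEngineState(
        user=user,
        hazards=[HazardState(disc=hazard, filled=True, activation_time=0.0)],
        next_spawn_time=config.spawn_interval,
        rng=np.random.default_rng(0),
    )


class ScriptedController:
    """Replays a fixed pointer position (or sequence) for engine tests."""

    def __init__(self, pointer=None):
        self._pointer = pointer

    def reset(self, trial_seed):
        pass

    def pointer(self, state, config):
        if self._pointer is not None:
            return self._pointer
        return state.user.center


def expected_correct_by_enumeration(k: int, n_squares: int = 10, n_targets: int = 5) -> float:
    """Independent oracle: exhaustive enumeration of the capacity-k policy.

    k targets are known; the remaining n_targets - k picks are a uniform
    subset of the n_squares - k unidentified squares, of which
    n_targets - k are targets.  Enumerate all fill subsets and average the
    number of targets hit.
    """
    from itertools import combinations

    remaining = n_squares - k
    remaining_targets = n_targets - k
    n_fill = n_targets - k
    if n_fill == 0:
        return float(k)
    # squares 0..remaining_targets-1 are the unidentified targets
    total = 0
    count = 0
    for subset in combinations(range(remaining), n_fill):
        total += sum(1 for s in subset if s < remaining_targets)
        count += 1
    return k + total / count


def ols_oracle(y, x):
    """Textbook normal-equations OLS, independent of the package path."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    xtx = design.T @ design
    coef = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ coef
    rss = float(resid @ resid)
    df = n - design.shape[1]
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * rss / df)
    return coef, se, rss
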