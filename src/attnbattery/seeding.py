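"""Counter-based deterministic seed derivation.

Every random draw in the battery flows from a session-level ``master_seed``
through :func:`derive_seed`, which hashes ``(master_seed, task_code,
counter)`` with :class:`numpy.random.SeedSequence`.  No global RNG state is
used anywhere, so each trial is independently reproducible from its
(task, index) coordinates alone.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TASK_CODES", "derive_seed", "rng_from_seed"]

# Stable small integers namespacing the per-task seed streams.
TASK_CODES = {"MOA": 1, "MOT": 2, "DSST": 3, "COHORT": 4, "AGENT": 5}


def derive_seed(master_seed: int, task_code: int, counter: int) -> int:
    """Derive a 63-bit sub-seed from (master_seed, task_code, counter)."""
    ss = np.random.SeedSequence([int(master_seed), int(task_code), int(counter)])
    return int(ss.generate_state(1, np.uint64)[0] >> 1)


def rng_from_seed(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))
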