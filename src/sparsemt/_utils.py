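"""Small shared helpers: rounding and seed derivation conventions."""

from __future__ import annotations

import math

import numpy as np

MAX_SEED = 2**31 - 1


def round_half_away(x: float) -> int:
    """Round half away from zero; the fixed convention for all count arithmetic.

    Python's built-in round() is banker's rounding (round(0.5) == 0), which
    would make split and removal counts depend on parity.
    """
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def derive_seed(*keys: int) -> int:
    """Deterministically derive a child seed (< 2**31) from integer keys."""
    ss = np.random.SeedSequence([int(k) & MAX_SEED for k in keys])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & MAX_SEED
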