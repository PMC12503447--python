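"""Small shared helpers: display rounding and seed derivation."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

_SEED_MOD = 2**31


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of clinical tables.

    Python's built-in ``round`` uses banker's rounding (49.25 -> 49.2); the
    frequency/mortality tables this package reproduces round half up
    (49.25 -> 49.3), so display formatting goes through this helper.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed: ``master_seed + index`` (mod 2^31).

    Keeps every derived seed individually reproducible and in the range
    accepted by all numpy bit generators.
    """
    return (int(master_seed) + int(index)) % _SEED_MOD
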