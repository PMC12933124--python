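"""Shared display and numerical conventions.

Printed summary figures in the cryo-ET meta-analysis literature round
half-values away from zero (a 65/26/8/1 percent split, tomogram counts of
31.8 -> 32), whereas Python's built-in ``round`` uses banker's rounding.
These helpers centralise the conventions so every module reports the same
way; full precision is always retained internally.
"""

from __future__ import annotations

import math

#: Smallest p-value ever reported; smaller values are floored rather than
#: collapsing to 0.0 (chi-square / normal survival functions underflow well
#: before this for the sample sizes handled here).
P_VALUE_FLOOR = 1e-300


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_to_half(x: float) -> float:
    """Round to the nearest 0.5 (used for sub-unit cells-per-lamella)."""
    return round_half_away(2.0 * x) / 2.0


def floor_p(p: float) -> float:
    """Clamp a p-value into (P_VALUE_FLOOR, 1]."""
    return min(1.0, max(float(p), P_VALUE_FLOOR))
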