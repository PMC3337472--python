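"""Small numeric helpers used across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ties away from zero (manuscript-style rounding).

    Python's built-in ``round`` rounds ties to even, which turns 1.875 into
    1.88 at one decimal; headline screen statistics are conventionally
    reported with ties away from zero (1.875 -> 1.9), so we do that
    explicitly via Decimal.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_half_away_int(x: float) -> int:
    """``round_half_away`` to an integer."""
    return int(round_half_away(x, 0))


def percent_report(fraction: float) -> int:
    """A probability rendered as a whole-number percentage (0.0768 -> 8)."""
    return round_half_away_int(100.0 * fraction)
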