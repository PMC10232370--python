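"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up at the displayed precision (2.25 -> 2.3 at 1)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100·num/den, rounded half-up; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, decimals)
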