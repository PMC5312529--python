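"""Small shared helpers: round-half-up formatting used by every rendered table."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of clinical report tables).

    Python's built-in ``round`` is banker's rounding; report tables round 33.85
    to 33.9, not 33.8.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denom: int, ndigits: int = 1) -> float:
    """Percentage rounded half-up, e.g. pct(22, 65) -> 33.8."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * count / denom, ndigits)


def fmt_count_pct(count: int, denom: int) -> str:
    """Render ``n (p%)`` cells, e.g. '22 (33.8)'."""
    return f"{count} ({pct(count, denom):.1f})"
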