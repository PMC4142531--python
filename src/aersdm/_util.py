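"""Small numeric helpers shared across the pipeline."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, like the printed tables.

    Python's built-in ``round`` is banker's rounding; report percentages
    here follow the half-up convention (0.5 -> 1, 1.45 -> 1.5 at one
    decimal).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 0) -> float | None:
    """Percentage ``100 * numerator / denominator`` rounded half-up.

    Returns None for a zero denominator (undefined, not zero).
    """
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, ndigits)
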