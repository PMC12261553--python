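"""Half-up decimal rounding, matching how clinical tables are printed."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (0.05 -> 0.1, not 0.0)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage rounded half-up; NaN for a zero denominator."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, ndigits)
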