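"""Presentation rounding.

All engine arithmetic is carried out at full float precision; dollar figures
and percentages are rounded only when a report is rendered.  Rounding is
half-up (ties away from zero), matching how the published summary tables
round, not banker's rounding.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, digits: int = 0) -> float:
    """Round ``x`` to ``digits`` decimal places, ties away from zero.

    Returns an int when ``digits`` is 0.
    """
    q = Decimal(1).scaleb(-digits)
    r = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return int(r) if digits == 0 else float(r)
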