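"""Display rounding and small parsing helpers shared across modules.

All pooling arithmetic is carried at full float precision; rounding is a
display concern only.  Bench worksheets round half-up (2.455 -> 2.46), which
differs from Python's banker's rounding, so we go through ``decimal``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half away from zero to ``ndigits`` decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def parse_weight(text) -> float:
    """Parse an expected-yield weight written as a decimal or a fraction.

    Pooling worksheets write weights in several idioms: ``0.2``, ``1/7``,
    or plain integers used as ratio terms (``5`` against ``1``).  All are
    reduced to a positive float; normalisation happens at pool level.
    """
    if isinstance(text, (int, float)):
        w = float(text)
    else:
        s = str(text).strip()
        w = float(Fraction(s)) if "/" in s else float(s)
    if not w > 0:
        raise ValueError(f"weight must be > 0, got {text!r}")
    return w


def parse_ratio(text: str) -> tuple[float, ...]:
    """Parse a ratio expression like ``'5:1'`` or ``'1:2'`` into terms."""
    parts = [p.strip() for p in str(text).split(":")]
    if len(parts) < 2:
        raise ValueError(f"ratio needs at least two terms, got {text!r}")
    terms = tuple(float(p) for p in parts)
    if any(t <= 0 for t in terms):
        raise ValueError(f"ratio terms must be > 0, got {text!r}")
    return terms


def parse_window(text: str) -> tuple[float, float]:
    """Parse a size window written ``'420:520'`` (bp)."""
    lo, hi = (float(p) for p in str(text).split(":"))
    return lo, hi
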