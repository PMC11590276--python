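"""Exact-cent money arithmetic.

All pricing rules operate on integer cents; floats appear only at the API
boundary (AUD) and in statistical models. Rounding to the cent is
half-away-from-zero so that repeated inflation of a catalogue is stable.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

CENTS = 100


def to_cents(aud: float | int | str | Decimal) -> int:
    """Convert an AUD amount to integer cents, rounding half away from zero."""
    d = Decimal(str(aud)) * CENTS
    return int(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def to_aud(cents: int) -> float:
    return cents / CENTS


def scale_cents(cents: int, factor: float) -> int:
    """Multiply a cent amount by a scalar (e.g. an inflation index), to the cent."""
    d = Decimal(cents) * Decimal(str(factor))
    return int(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
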