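"""Shared helpers: error types, half-up rounding, interval parsing."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


class InputError(ValueError):
    """Malformed or inconsistent user-supplied data."""


class ConfigError(ValueError):
    """Invalid configuration (unknown matrix, species, field, ...)."""


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), unlike banker's rounding.

    Percentages in tabular reports are rounded this way so that recomputing
    a printed percentage from its count and denominator is reproducible.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, ndigits: int = 1) -> float:
    """100*count/denominator rounded half-up; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, ndigits)
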