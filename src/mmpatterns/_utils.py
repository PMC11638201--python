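"""Shared helpers: rounding, errors, logging."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

logger = logging.getLogger("mmpatterns")


class SchemaError(ValueError):
    """Input table is structurally incompatible (e.g. missing column)."""


class ValidationError(ValueError):
    """A record or matrix violates a domain invariant."""


class ConfigError(ValueError):
    """A configuration value is out of its allowed range."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of printed survey tables.

    Python's builtin round() is banker's rounding (17.65 -> 17.6); survey
    reports round halves up (17.65 -> 17.7), so percentages are rounded here.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage with non-positive denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
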