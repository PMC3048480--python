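"""Shared helpers: unit normalization, calendar-free age arithmetic, display rounding.

Internal canonical units are milligrams for drug mass, kilograms for body
weight, and days for age.  Display-layer code converts back out; keeping a
single canonical unit internally removes the g/mg and lb/kg confusion error
classes entirely from the core logic.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

# Fixed, calendar-free conversion factors.
DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375  # DAYS_PER_YEAR / 12

LB_PER_KG = 2.20462

_MASS_FACTORS_TO_MG = {
    "mg": 1.0,
    "g": 1000.0,
    "mcg": 0.001,
    "ug": 0.001,
}


class UnitError(ValueError):
    """An unparseable or unsupported mass/weight expression."""


def parse_mass_mg(value) -> float:
    """Parse a mass expression into milligrams.

    Accepts a bare number (interpreted as mg) or a string such as
    ``"100 mg"``, ``"1 g"``, ``"1g"``.
    """
    if isinstance(value, (int, float)):
        mg = float(value)
    elif isinstance(value, str):
        text = value.strip().lower()
        num, unit = _split_unit(text)
        if unit == "":
            unit = "mg"
        if unit not in _MASS_FACTORS_TO_MG:
            raise UnitError(f"unsupported mass unit {unit!r} in {value!r}")
        mg = num * _MASS_FACTORS_TO_MG[unit]
    else:
        raise UnitError(f"cannot parse mass from {value!r}")
    if not mg > 0:
        raise UnitError(f"mass must be positive, got {value!r}")
    return mg


def _split_unit(text: str) -> tuple[float, str]:
    idx = len(text)
    for i, ch in enumerate(text):
        if ch.isalpha():
            idx = i
            break
    try:
        num = float(text[:idx].strip())
    except ValueError as exc:
        raise UnitError(f"cannot parse number from {text!r}") from exc
    return num, text[idx:].strip()


def years_to_days(years: float) -> float:
    return years * DAYS_PER_YEAR


def months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (5 rounds away from zero), for display values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
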