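"""Patient parameters, weight histories, pediatric classification, growth curves.

The engine reasons over six patient parameters: indication, care area,
chronological age, post-conceptual age, dosing weight, and renal impairment.
Dosing weight is deliberately distinct from the measured (actual) weight: it
is the clinician-chosen weight on which dose calculations are based, and only
physicians or physician extenders may enter or update it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._common import DAYS_PER_MONTH, DAYS_PER_YEAR

WEIGHT_KINDS = ("actual", "dosing")
WEIGHT_ENTRY_ROLES = ("physician", "physician_extender", "other")
#: roles permitted to enter or update patient weights
AUTHORIZED_WEIGHT_ROLES = ("physician", "physician_extender")

PEDIATRIC_AGE_LIMIT_DAYS = 14 * DAYS_PER_YEAR
PEDIATRIC_AGE_WEIGHT_LIMIT_DAYS = 18 * DAYS_PER_YEAR
PEDIATRIC_WEIGHT_LIMIT_KG = 45.0


class WeightEntryNotPermitted(PermissionError):
    """Weight mutation attempted by a role outside the authorized set."""


@dataclass(frozen=True)
class WeightRecord:
    value_kg: float
    timestamp: datetime
    kind: str  # actual | dosing
    entered_by_role: str = "physician"

    def __post_init__(self) -> None:
        if not self.value_kg > 0:
            raise ValueError("weight must be positive")
        if self.kind not in WEIGHT_KINDS:
            raise ValueError(f"weight kind must be one of {WEIGHT_KINDS}")
        if self.entered_by_role not in WEIGHT_ENTRY_ROLES:
            raise ValueError(f"entered_by_role must be one of {WEIGHT_ENTRY_ROLES}")


@dataclass
class Patient:
    patient_id: str
    chronological_age_days: int
    care_area: str
    sex: Optional[str] = None  # "M" | "F", used only for growth-curve selection
    post_conceptual_age_days: Optional[int] = None
    renal_impairment: Optional[str] = None  # "impaired" | "not_impaired" | None (unknown)
    actual_weights: list = field(default_factory=list)
    dosing_weights: list = field(default_factory=list)
    allergies: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.chronological_age_days < 0:
            raise ValueError("age must be non-negative")
        if (
            self.post_conceptual_age_days is not None
            and self.post_conceptual_age_days < self.chronological_age_days
        ):
            raise ValueError("post-conceptual age cannot precede chronological age")

    def _history(self, kind: str) -> list:
        if kind == "actual":
            return self.actual_weights
        if kind == "dosing":
            return self.dosing_weights
        raise ValueError(f"unknown weight kind {kind!r}")

    def add_weight(self, record: WeightRecord) -> None:
        """Append a weight record, enforcing the entry-role policy."""
        if record.entered_by_role not in AUTHORIZED_WEIGHT_ROLES:
            raise WeightEntryNotPermitted(
                f"role {record.entered_by_role!r} may not enter patient weights"
            )
        history = self._history(record.kind)
        history.append(record)
        history.sort(key=lambda r: r.timestamp)

    def current_weight(self, kind: str, as_of: Optional[datetime] = None) -> Optional[WeightRecord]:
        """Latest record of ``kind`` at or before ``as_of`` (None = end of history)."""
        best = None
        for record in self._history(kind):
            if as_of is not None and record.timestamp > as_of:
                continue
            if best is None or record.timestamp >= best.timestamp:
                best = record
        return best


def current_weight(patient: Patient, kind: str, as_of: Optional[datetime] = None):
    """Latest weight record of ``kind`` at or before ``as_of``; ``None`` when
    absent (the signal for the mandatory dosing-weight prompt)."""
    return patient.current_weight(kind, as_of)


@dataclass(frozen=True)
class PediatricStatus:
    """Outcome of classifying a patient, with a weight-needed signal.

    ``weight_needed`` is raised when the classification fell through to the
    age-and-weight branch but no weight was on file; such a patient is
    classified as not pediatric, and callers should prompt for a weight.
    """

    pediatric: bool
    weight_needed: bool = False


def classify_pediatric(age_days: float, weight_kg: Optional[float] = None) -> bool:
    """Apply the pediatric definition: age < 14 y, or age < 18 y and weight < 45 kg.

    Age alone (not location) defines the population, so children cared for on
    adult floors are still captured.  Both inequalities are strict.
    """
    if age_days < 0:
        raise ValueError("age must be non-negative")
    if age_days < PEDIATRIC_AGE_LIMIT_DAYS:
        return True
    if age_days < PEDIATRIC_AGE_WEIGHT_LIMIT_DAYS:
        return weight_kg is not None and weight_kg < PEDIATRIC_WEIGHT_LIMIT_KG
    return False


def classify_patient(patient: Patient, as_of: Optional[datetime] = None) -> PediatricStatus:
    """Classify a patient, preferring the dosing weight over the actual weight."""
    record = patient.current_weight("dosing", as_of) or patient.current_weight("actual", as_of)
    weight = record.value_kg if record is not None else None
    pediatric = classify_pediatric(patient.chronological_age_days, weight)
    weight_needed = (
        weight is None
        and PEDIATRIC_AGE_LIMIT_DAYS <= patient.chronological_age_days < PEDIATRIC_AGE_WEIGHT_LIMIT_DAYS
    )
    return PediatricStatus(pediatric=pediatric, weight_needed=weight_needed)


# ---------------------------------------------------------------------------
# Age unit translation
# ---------------------------------------------------------------------------

_AGE_UNIT_DAYS = {"day": 1.0, "month": DAYS_PER_MONTH, "year": DAYS_PER_YEAR}


def age_display(age_days: int) -> str:
    """Render an age in the clinically conventional unit.

    Days for newborns (< 31 days), whole months below 2 years, whole years
    (floored) beyond — mirroring how clinicians state pediatric ages.
    """
    if age_days < 0:
        raise ValueError("age must be non-negative")
    if age_days < 31:
        value, unit = age_days, "day"
    elif age_days < 24 * DAYS_PER_MONTH:
        value, unit = int(age_days / DAYS_PER_MONTH), "month"
    else:
        value, unit = int(age_days / DAYS_PER_YEAR), "year"
    plural = "" if value == 1 else "s"
    return f"{value} {unit}{plural}"


def parse_age_display(rendered: str) -> int:
    """Invert :func:`age_display` to a representative day count.

    Returns the smallest day count consistent with the rendered value
    (ceiling of the unit conversion), which re-renders identically.
    """
    match = re.fullmatch(r"\s*(\d+)\s+(day|month|year)s?\s*", rendered)
    if match is None:
        raise ValueError(f"cannot parse age string {rendered!r}")
    value = int(match.group(1))
    return math.ceil(value * _AGE_UNIT_DAYS[match.group(2)])


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


class GrowthCurveSupportError(ValueError):
    """Requested age lies outside the growth-curve table's age support."""


class GrowthCurves:
    """Age- and sex-conditional weight distribution (normal by age).

    Backed by a tabular file with columns ``age_days, sex, median_kg, sd_kg``;
    median and SD are linearly interpolated in age.  Any table of the same
    shape (e.g., an LMS-derived export) can be dropped in; the bundled tables
    are synthetic.
    """

    COLUMNS = ("age_days", "sex", "median_kg", "sd_kg")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"growth-curve table missing columns {sorted(missing)}")
        self._by_sex = {}
        for sex, group in table.groupby("sex"):
            group = group.sort_values("age_days")
            ages = group["age_days"].to_numpy(dtype=float)
            if len(ages) < 2 or np.any(np.diff(ages) <= 0):
                raise ValueError(f"growth curve for sex {sex!r} needs strictly increasing ages")
            self._by_sex[str(sex)] = (
                ages,
                group["median_kg"].to_numpy(dtype=float),
                group["sd_kg"].to_numpy(dtype=float),
            )
        if not self._by_sex:
            raise ValueError("growth-curve table is empty")

    @classmethod
    def from_csv(cls, path) -> "GrowthCurves":
        return cls(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for sex, (ages, med, sd) in sorted(self._by_sex.items()):
            frames.append(
                pd.DataFrame(
                    {"age_days": ages, "sex": sex, "median_kg": med, "sd_kg": sd}
                )
            )
        return pd.concat(frames, ignore_index=True)[list(self.COLUMNS)]

    def support(self, sex: str) -> tuple:
        ages = self._curve(sex)[0]
        return float(ages[0]), float(ages[-1])

    def _curve(self, sex: str):
        try:
            return self._by_sex[sex]
        except KeyError:
            raise GrowthCurveSupportError(f"no growth curve for sex {sex!r}") from None

    def median_sd(self, age_days: float, sex: str) -> tuple:
        ages, med, sd = self._curve(sex)
        if not ages[0] <= age_days <= ages[-1]:
            raise GrowthCurveSupportError(
                f"age {age_days} days outside curve support [{ages[0]}, {ages[-1]}]"
            )
        return (
            float(np.interp(age_days, ages, med)),
            float(np.interp(age_days, ages, sd)),
        )


def growth_percentile(weight_kg: float, age_days: float, sex: str, curves: GrowthCurves) -> float:
    """Weight percentile under the curve's age-conditional normal model.

    Strictly increasing in weight at fixed age; the curve's own median maps
    to exactly the 50th percentile.  Raises
    :class:`GrowthCurveSupportError` outside the table's age support.
    """
    if not weight_kg > 0:
        raise ValueError("weight must be positive")
    median, sd = curves.median_sd(age_days, sex)
    return 100.0 * float(stats.norm.cdf((weight_kg - median) / sd))
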