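"""Synthetic inputs: growth curves, patient cohorts, error-injected order streams.

Everything the other modules consume can be generated here deterministically
from a single master seed (per-component child seeds are derived from it, so
any stage reproduces in isolation).  The growth model is an age-conditional
normal with log-linear median interpolation between knots — the simplest
model that is strictly increasing in age and percentile-self-consistent.  It
is explicitly NOT a claim about real anthropometry; real curve tables of the
same shape can be substituted.

The order stream injects the classic pediatric ordering errors at
configurable rates, at most one per event so interception attribution stays
unambiguous:

* ``lb_for_kg`` — a weight miskeyed in pounds instead of kilograms
  (entered value = true weight x 2.20462);
* ``tenfold_dose`` — a tenfold dose slip (entered dose = 10 x correct);
* ``stale_weight`` — an order dosed off a superseded dosing weight.

Each event records its injected error and ground-truth dose so
:func:`score_interception` can measure, per error mode, the fraction caught
by at least one alert or bounds check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._common import LB_PER_KG, years_to_days
from .alerts import check_weight_entry, weight_adjust_reminders
from .engine import OrderRecord, check_manual_dose, compute_dose, resolve
from .knowledge_base import KnowledgeBase, load_kb
from .patients import GrowthCurves, Patient, WeightRecord

#: simulation epoch; all synthetic timestamps are offsets from this instant
EPOCH = datetime(2008, 3, 1, 8, 0, 0)

#: care-area mix proportional to the six pediatric units' bed counts
DEFAULT_CARE_AREA_MIX = {
    "general": 61 / 187,
    "transitional": 16 / 187,
    "picu": 16 / 187,
    "bmt": 16 / 187,
    "nicu": 65 / 187,
    "cardiac_icu": 13 / 187,
}

#: plausible chronological-age spans per care area (days)
_AGE_SPANS = {
    "nicu": (0, 28),
    "transitional": (14, 730),
    "picu": (30, int(years_to_days(16))),
    "bmt": (365, int(years_to_days(16))),
    "cardiac_icu": (0, int(years_to_days(10))),
    "general": (30, int(years_to_days(17))),
}

ERROR_MODES = ("lb_for_kg", "tenfold_dose", "stale_weight")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_patients: int = 150
    n_orders: int = 1000
    horizon_days: int = 30
    care_area_mix: dict = field(default_factory=lambda: dict(DEFAULT_CARE_AREA_MIX))
    #: error-injection rates, one draw per order event, mutually exclusive
    p_lb_for_kg: float = 0.05
    p_tenfold_dose: float = 0.05
    p_stale_weight: float = 0.05
    #: fraction of deliberately non-pediatric patients (for suppression tests)
    adult_fraction: float = 0.0
    #: cadence (days) at which the synthetic cohort re-enters dosing weights
    dosing_update_interval: int = 3

    def __post_init__(self) -> None:
        total = sum(self.care_area_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"care-area mix must sum to 1, got {total}")
        for name in ("p_lb_for_kg", "p_tenfold_dose", "p_stale_weight", "adult_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_lb_for_kg + self.p_tenfold_dose + self.p_stale_weight > 1.0:
            raise ValueError("error rates may not sum past 1")


@dataclass(frozen=True)
class OrderEvent:
    timestamp: datetime
    patient_id: str
    drug_id: str
    inputs: dict
    entered_dose_mg: float
    true_dose_mg: float
    injected_error: Optional[str] = None
    entered_weight_kg: Optional[float] = None  # the miskeyed value, lb_for_kg only
    region_id: Optional[str] = None
    weight_used: Optional[WeightRecord] = None


def _child_rngs(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

# Median-weight knots (age_days -> kg) for the synthetic curves.
_MEDIAN_KNOTS = {
    "M": [
        (0, 3.53), (30, 4.45), (91, 6.09), (182, 7.93), (365, 9.65), (547, 11.0),
        (730, 12.2), (1096, 14.3), (1461, 16.3), (1826, 18.3), (2557, 23.0),
        (3287, 28.5), (3652, 32.0), (4018, 36.0), (4383, 40.5), (4748, 45.5),
        (5113, 51.0), (5479, 56.5), (5844, 61.0), (6209, 64.5), (6575, 67.0),
    ],
    "F": [
        (0, 3.40), (30, 4.25), (91, 5.65), (182, 7.30), (365, 8.95), (547, 10.3),
        (730, 11.5), (1096, 13.7), (1461, 15.7), (1826, 17.7), (2557, 22.5),
        (3287, 28.0), (3652, 32.5), (4018, 37.0), (4383, 41.5), (4748, 45.0),
        (5113, 48.0), (5479, 51.0), (5844, 53.5), (6209, 55.5), (6575, 57.0),
    ],
}

#: age grid the curve table is written on
_CURVE_AGES = np.concatenate(
    [np.arange(0, 61, 2), np.arange(70, 731, 10), np.arange(780, 6576, 50), [6575]]
)


def make_growth_curves(seed: int = 0) -> GrowthCurves:
    """Deterministic synthetic growth-curve table for both sexes, 0-18 y.

    Median weight is strictly increasing in age (log-linear between knots);
    SD grows from 11% of the median at birth to 16% at 18 y.  The seed
    applies a small global scale (±2%) per sex, emulating center-to-center
    reference differences without breaking monotonicity.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    frames = []
    ages = np.unique(_CURVE_AGES).astype(float)
    sd_frac = 0.11 + 0.05 * ages / 6575.0
    for sex in ("M", "F"):
        knots = np.array(_MEDIAN_KNOTS[sex], dtype=float)
        scale = 1.0 + rng.uniform(-0.02, 0.02)
        median = np.exp(np.interp(ages, knots[:, 0], np.log(knots[:, 1] * scale)))
        frames.append(
            pd.DataFrame(
                {
                    "age_days": ages,
                    "sex": sex,
                    "median_kg": np.round(median, 4),
                    "sd_kg": np.round(sd_frac * median, 4),
                }
            )
        )
    return GrowthCurves(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Patient cohort
# ---------------------------------------------------------------------------


def simulate_patients(config: SimulationConfig, curves: GrowthCurves) -> list:
    """Generate a patient roster with daily weight trajectories.

    Each child tracks a growth-percentile channel (z drawn uniformly in
    [-2, 2], i.e. roughly the 2nd-98th percentile band) with a small AR(1)
    wobble, so day-over-day changes stay well under 5% absent injected
    errors.  Actual weights are recorded daily; dosing weights every
    ``dosing_update_interval`` days, mirroring unit practice.  With
    ``adult_fraction`` > 0, that share of the roster is generated as
    non-pediatric adults (for suppression/redirection testing).
    """
    rng = _child_rngs(config.seed, 3)[1]
    areas = sorted(config.care_area_mix)
    probs = np.array([config.care_area_mix[a] for a in areas])
    probs = probs / probs.sum()
    roster = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        if rng.random() < config.adult_fraction:
            patient = _make_adult(pid, sex, rng, config)
        else:
            area = str(rng.choice(areas, p=probs))
            patient = _make_child(pid, sex, area, rng, config, curves)
        roster.append(patient)
    return roster


def _make_child(pid, sex, area, rng, config, curves) -> Patient:
    lo, hi = _AGE_SPANS[area]
    hi = min(hi, 6575 - config.horizon_days - 1)
    age0 = int(rng.integers(lo, hi + 1))
    patient = Patient(patient_id=pid, chronological_age_days=age0, care_area=area, sex=sex)
    if area == "nicu":
        patient.post_conceptual_age_days = age0 + int(rng.integers(245, 295))
    z = rng.uniform(-2.0, 2.0)
    wobble = 0.0
    for day in range(config.horizon_days):
        median, sd = curves.median_sd(age0 + day, sex)
        wobble = float(np.clip(0.9 * wobble + rng.uniform(-0.005, 0.005), -0.02, 0.02))
        weight = round((median + z * sd) * float(np.exp(wobble)), 2)
        stamp = EPOCH + timedelta(days=day)
        patient.add_weight(WeightRecord(weight, stamp, "actual", "physician_extender"))
        if day % config.dosing_update_interval == 0:
            patient.add_weight(WeightRecord(weight, stamp + timedelta(hours=1), "dosing", "physician"))
    return patient


def _make_adult(pid, sex, rng, config) -> Patient:
    age0 = int(rng.integers(int(years_to_days(19)), int(years_to_days(40))))
    patient = Patient(
        patient_id=pid, chronological_age_days=age0, care_area="non_pediatric", sex=sex
    )
    weight = round(float(rng.normal(75.0, 12.0)), 2)
    weight = max(weight, 45.0)
    for day in range(0, config.horizon_days, config.dosing_update_interval):
        stamp = EPOCH + timedelta(days=day)
        patient.add_weight(WeightRecord(weight, stamp, "actual", "physician_extender"))
        patient.add_weight(WeightRecord(weight, stamp + timedelta(hours=1), "dosing", "physician"))
    return patient


# ---------------------------------------------------------------------------
# Order stream
# ---------------------------------------------------------------------------

_FALLBACK_PER_KG_MG = 75.0  # mid-range sanctioned per-kg dose for manual-path ground truth


def _pick_inputs(patient: Patient, kb: KnowledgeBase, rng) -> dict:
    if kb.order_set_indications and rng.random() < 0.15:
        order_set = str(rng.choice(sorted(kb.order_set_indications)))
        return {"order_set": order_set}
    if patient.care_area in ("general", "non_pediatric") and rng.random() < 0.3:
        return {"indication": "osteomyelitis"}
    return {"indication": "meningitis"}


def simulate_order_stream(roster: list, kb: KnowledgeBase, config: SimulationConfig) -> list:
    """Emit order events for KB drugs with errors injected at the configured
    rates and ground-truth doses attached.

    When the resolver identifies a single dosing region the ground truth is
    that region's capped-and-rounded dose; otherwise the event follows the
    manual path with a mid-range weight-based ground truth.
    """
    rng = _child_rngs(config.seed, 3)[2]
    drug_ids = sorted(kb.medications)
    if not drug_ids:
        raise ValueError("knowledge base has no medications to order")
    first_day = min(config.dosing_update_interval + 1, config.horizon_days - 1)
    events = []
    for _ in range(config.n_orders):
        patient = roster[int(rng.integers(len(roster)))]
        drug_id = str(rng.choice(drug_ids))
        day = int(rng.integers(first_day, config.horizon_days))
        stamp = EPOCH + timedelta(days=day, hours=4)
        inputs = _pick_inputs(patient, kb, rng)
        weight = patient.current_weight("dosing", stamp)
        outcome = resolve(kb, patient, drug_id, provided=inputs, as_of=stamp)
        if outcome.status == "single":
            proposal = compute_dose(kb, outcome.region, weight)
            true_dose = proposal.rounded_dose_mg
            region_id = outcome.region.region_id
        else:
            true_dose = _FALLBACK_PER_KG_MG * weight.value_kg
            region_id = None

        u = rng.random()
        error: Optional[str] = None
        entered_dose = true_dose
        entered_weight = None
        weight_used = weight
        if u < config.p_lb_for_kg:
            error = "lb_for_kg"
            entered_weight = round(weight.value_kg * LB_PER_KG, 2)
        elif u < config.p_lb_for_kg + config.p_tenfold_dose:
            error = "tenfold_dose"
            entered_dose = 10.0 * true_dose
        elif u < config.p_lb_for_kg + config.p_tenfold_dose + config.p_stale_weight:
            error = "stale_weight"
            history = [r for r in patient.dosing_weights if r.timestamp < weight.timestamp]
            if history:
                weight_used = history[0]
            else:  # no superseded weight exists; leave the event clean
                error = None
        events.append(
            OrderEvent(
                timestamp=stamp,
                patient_id=patient.patient_id,
                drug_id=drug_id,
                inputs=inputs,
                entered_dose_mg=float(entered_dose),
                true_dose_mg=float(true_dose),
                injected_error=error,
                entered_weight_kg=entered_weight,
                region_id=region_id,
                weight_used=weight_used,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Interception scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterceptionMetric:
    n_injected: int
    n_intercepted: int

    @property
    def fraction(self) -> float:
        return self.n_intercepted / self.n_injected


def score_interception(
    events: list, kb: KnowledgeBase, roster: list, curves: GrowthCurves
) -> dict:
    """Replay injected-error events through the alert and bounds machinery.

    Per error mode, the fraction of events intercepted by at least one
    safeguard: weight-entry alerts for pound-for-kilogram miskeys, the
    min/max bounds check for tenfold doses, weight-adjust reminders for
    stale-weight orders.  Modes with no injections are absent from the
    result.
    """
    by_id = {p.patient_id: p for p in roster}
    tallies = {mode: [0, 0] for mode in ERROR_MODES}
    for event in events:
        mode = event.injected_error
        if mode is None:
            continue
        patient = by_id[event.patient_id]
        config = kb.alert_config(patient.care_area)
        if mode == "lb_for_kg":
            candidate = WeightRecord(
                event.entered_weight_kg, event.timestamp, "dosing", "physician"
            )
            caught = bool(check_weight_entry(patient, candidate, curves, config))
        elif mode == "tenfold_dose":
            verdict = check_manual_dose(
                kb, event.drug_id, patient, event.entered_dose_mg, as_of=event.timestamp
            )
            caught = verdict == "out_of_bounds"
        else:  # stale_weight
            order = OrderRecord(
                order_id=f"replay-{event.patient_id}-{event.timestamp:%d%H}",
                drug_id=event.drug_id,
                dose_mg=event.entered_dose_mg,
                route="IV",
                frequency="q8h",
                timestamp=event.timestamp,
                status="accepted",
                region_id=event.region_id,
                manual=event.region_id is None,
                weight_used=event.weight_used,
            )
            caught = bool(weight_adjust_reminders([order], patient, as_of=event.timestamp))
        tallies[mode][0] += 1
        tallies[mode][1] += int(caught)
    return {
        mode: InterceptionMetric(n_injected=n, n_intercepted=k)
        for mode, (n, k) in tallies.items()
        if n > 0
    }


# ---------------------------------------------------------------------------
# Bundled fixtures and roster files
# ---------------------------------------------------------------------------

_DATA = resources.files("peddose") / "data"

FIXTURE_KB = "ampicillin_kb.yaml"
FIXTURE_COUNTS = "unit_period_counts.csv"
FIXTURE_CURVES = "growth_curves_synthetic.csv"


def fixture_path(name: str) -> Path:
    return Path(str(_DATA / name))


def load_fixture_kb() -> KnowledgeBase:
    """The bundled single-drug (ampicillin) knowledge base."""
    return load_kb(fixture_path(FIXTURE_KB))


def load_fixture_curves() -> GrowthCurves:
    """The bundled synthetic growth-curve table."""
    return GrowthCurves.from_csv(fixture_path(FIXTURE_CURVES))


def install_fixtures(target_dir) -> list:
    """Copy the bundled fixtures into a directory; returns the paths written."""
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    written = []
    for name in (FIXTURE_KB, FIXTURE_COUNTS, FIXTURE_CURVES):
        dest = target / name
        dest.write_bytes(fixture_path(name).read_bytes())
        written.append(dest)
    return written


def roster_to_document(roster: list) -> dict:
    def weights(records):
        return [
            {
                "value_kg": r.value_kg,
                "timestamp": r.timestamp.isoformat(),
                "entered_by_role": r.entered_by_role,
            }
            for r in records
        ]

    return {
        "patients": [
            {
                "patient_id": p.patient_id,
                "chronological_age_days": p.chronological_age_days,
                "post_conceptual_age_days": p.post_conceptual_age_days,
                "sex": p.sex,
                "care_area": p.care_area,
                "renal_impairment": p.renal_impairment,
                "allergies": sorted(p.allergies),
                "actual_weights": weights(p.actual_weights),
                "dosing_weights": weights(p.dosing_weights),
            }
            for p in roster
        ]
    }


def write_roster(roster: list, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(roster_to_document(roster), fh, sort_keys=False)


def load_roster(path) -> list:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    roster = []
    for raw in doc.get("patients", []):
        patient = Patient(
            patient_id=str(raw["patient_id"]),
            chronological_age_days=int(raw["chronological_age_days"]),
            care_area=str(raw["care_area"]),
            sex=raw.get("sex"),
            post_conceptual_age_days=raw.get("post_conceptual_age_days"),
            renal_impairment=raw.get("renal_impairment"),
            allergies=set(raw.get("allergies") or []),
        )
        for kind in ("actual", "dosing"):
            for rec in raw.get(f"{kind}_weights") or []:
                patient.add_weight(
                    WeightRecord(
                        value_kg=float(rec["value_kg"]),
                        timestamp=datetime.fromisoformat(rec["timestamp"]),
                        kind=kind,
                        entered_by_role=rec.get("entered_by_role", "physician"),
                    )
                )
        roster.append(patient)
    return roster
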