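"""Dosing-region resolution, dose computation, bounds checking, order placement.

Resolution filters a drug's dosing regions by every patient criterion whose
value is known (age, weight, and care area are always known; indication,
gestational age, and renal status may require prompting).  Exactly one
surviving region is presented for calculation; zero or multiple survivors
exit to manual entry, with no precedence heuristic.  A manual dose is guarded
by per-drug min/max bounds and, when aberrant, a double-entry override in
which the user must retype the exact value.  Every manually entered dose is
recorded in an append-only audit trail for knowledge-base gap review.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional

from .knowledge_base import (
    ANY,
    CriteriaSet,
    DosingRegion,
    KnowledgeBase,
    RoundingPolicy,
    regions_for,
)
from .patients import Patient, WeightRecord

#: prompt order for parameters the resolver may need from the user
PROMPTABLE_PARAMETERS = ("indication", "gestational_age", "renal_status")


class OrderBlocked(Exception):
    """Order placement refused (allergy gate or override protocol unmet)."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


class MissingDosingWeight(Exception):
    """Resolution attempted without a current dosing weight on file."""


@dataclass(frozen=True)
class MatchOutcome:
    """Result of resolving a drug against a patient's known parameters.

    status: ``single`` (one region — present it), ``none`` / ``multiple``
    (exit to manual entry), or ``needs_input`` (the listed parameters would
    narrow the surviving set and should be prompted for).
    """

    status: str
    matched: tuple = ()
    missing_inputs: tuple = ()

    def __post_init__(self) -> None:
        if self.status not in ("single", "none", "multiple", "needs_input"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "single") != (len(self.matched) == 1 and not self.missing_inputs):
            if self.status == "single":
                raise ValueError("status=single requires exactly one match")
        if (self.status == "needs_input") != bool(self.missing_inputs):
            raise ValueError("needs_input iff missing_inputs nonempty")

    @property
    def region(self):
        if self.status != "single":
            raise ValueError("no unique region for a non-single outcome")
        return self.matched[0]


@dataclass(frozen=True)
class DoseProposal:
    region_id: str
    raw_dose_mg: float
    capped_dose_mg: float
    rounded_dose_mg: float
    route: str
    frequency: str
    was_capped: bool
    was_rounded: bool
    unit: str = "mg"
    weight_used: Optional[WeightRecord] = None
    dose_count: Optional[int] = None
    prn: bool = False

    @property
    def final_dose_mg(self) -> float:
        return self.rounded_dose_mg


@dataclass(frozen=True)
class OrderRecord:
    order_id: str
    drug_id: str
    dose_mg: float
    route: str
    frequency: str
    timestamp: datetime
    status: str = "draft"  # draft | accepted
    region_id: Optional[str] = None  # None for manual orders
    manual: bool = False
    weight_used: Optional[WeightRecord] = None
    override_annotation: Optional[str] = None
    inputs: dict = field(default_factory=dict)  # prompted parameters at order time

    def __post_init__(self) -> None:
        if self.manual and self.region_id is not None:
            raise ValueError("manual orders carry no region_id")
        if self.status not in ("draft", "accepted"):
            raise ValueError(f"bad order status {self.status!r}")


@dataclass(frozen=True)
class AuditEntry:
    """One manual-dose event: patient snapshot, drug, dose, and why."""

    timestamp: datetime
    drug_id: str
    entered_dose_mg: float
    reason: str  # no_region | region_gap | override
    patient_snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reason not in ("no_region", "region_gap", "override"):
            raise ValueError(f"bad audit reason {self.reason!r}")

    def to_json_line(self) -> str:
        payload = {
            "timestamp": self.timestamp.isoformat(),
            "drug_id": self.drug_id,
            "entered_dose_mg": self.entered_dose_mg,
            "reason": self.reason,
            "patient": self.patient_snapshot,
        }
        return json.dumps(payload, sort_keys=True)


class AuditLog:
    """Append-only audit trail; one structured record per line."""

    def __init__(self, path=None):
        self.path = path
        self.entries: list = []

    def append(self, entry: AuditEntry) -> None:
        self.entries.append(entry)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(entry.to_json_line() + "\n")


def _patient_snapshot(patient: Patient, as_of: Optional[datetime]) -> dict:
    dosing = patient.current_weight("dosing", as_of)
    actual = patient.current_weight("actual", as_of)
    return {
        "patient_id": patient.patient_id,
        "age_days": patient.chronological_age_days,
        "post_conceptual_age_days": patient.post_conceptual_age_days,
        "care_area": patient.care_area,
        "renal_impairment": patient.renal_impairment,
        "dosing_weight_kg": dosing.value_kg if dosing else None,
        "actual_weight_kg": actual.value_kg if actual else None,
    }


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------


def _known_parameters(patient: Patient, provided: dict, kb: KnowledgeBase, as_of) -> dict:
    """Assemble the parameter map: always-known patient facts plus prompts.

    An order-set identifier in ``provided`` injects its mapped indication
    before filtering, so order-set-driven regions resolve without a prompt.
    """
    provided = dict(provided or {})
    weight = patient.current_weight("dosing", as_of)
    if weight is None:
        raise MissingDosingWeight(
            f"patient {patient.patient_id!r} has no current dosing weight; "
            "prompt for one before resolving"
        )
    params = {
        "age_days": float(patient.chronological_age_days),
        "weight_kg": weight.value_kg,
        "care_area": patient.care_area,
        "weight_record": weight,
    }
    order_set = provided.get("order_set")
    if order_set is not None:
        params["order_set"] = order_set
        mapped = kb.order_set_indications.get(order_set)
        if mapped is not None:
            params.setdefault("indication", mapped)
    if provided.get("indication") is not None:
        params["indication"] = provided["indication"]
    pca = provided.get("post_conceptual_age_days", patient.post_conceptual_age_days)
    if pca is not None:
        params["pca_days"] = float(pca)
    renal = provided.get("renal_status", patient.renal_impairment)
    if renal is not None:
        params["renal_status"] = renal
    return params


def _criteria_match_known(criteria: CriteriaSet, params: dict) -> bool:
    """Filter by every criterion whose patient value is known; unknown
    parameters do not filter (they may later be prompted for)."""
    if criteria.age_days is not None and not criteria.age_days.contains(params["age_days"]):
        return False
    if criteria.weight_kg is not None and not criteria.weight_kg.contains(params["weight_kg"]):
        return False
    if criteria.care_areas is not ANY and params["care_area"] not in criteria.care_areas:
        return False
    if "indication" in params and criteria.indications is not ANY:
        if params["indication"] not in criteria.indications:
            return False
    if "pca_days" in params and criteria.pca_days is not None:
        if not criteria.pca_days.contains(params["pca_days"]):
            return False
    if "renal_status" in params and criteria.renal_status != "any":
        if criteria.renal_status != params["renal_status"]:
            return False
    # order_set_context is the injection anchor for the order-set indication
    # pathway; selectivity comes from the indications criterion above, so an
    # order-set-scoped region survives while the indication is still unknown
    # (and will surface through the needs_input prompt).
    return True


_PARAM_KEYS = {
    "indication": "indication",
    "gestational_age": "pca_days",
    "renal_status": "renal_status",
}


def _constraint_token(criteria: CriteriaSet, parameter: str):
    if parameter == "indication":
        return criteria.indications if criteria.indications is ANY else criteria.indications
    if parameter == "gestational_age":
        return criteria.pca_days
    if parameter == "renal_status":
        return criteria.renal_status
    raise ValueError(parameter)


def _needed_parameters(surviving: Iterable[DosingRegion], params: dict) -> tuple:
    """Unknown parameters on which the surviving regions differ.

    A parameter is worth prompting for exactly when knowing it could shrink
    the surviving set — i.e., the survivors do not all share one constraint.
    """
    needed = []
    for parameter in PROMPTABLE_PARAMETERS:
        if _PARAM_KEYS[parameter] in params:
            continue
        tokens = {_constraint_token(r.criteria, parameter) for r in surviving}
        if len(tokens) > 1:
            needed.append(parameter)
    return tuple(needed)


def resolve(
    kb: KnowledgeBase,
    patient: Patient,
    drug_id: str,
    provided: Optional[dict] = None,
    as_of: Optional[datetime] = None,
) -> MatchOutcome:
    """Resolve a drug's dosing regions against a patient.

    Raises :class:`~peddose.knowledge_base.NotInFormularyError` for unknown
    drugs and :class:`MissingDosingWeight` when no dosing weight is on file
    (the caller must raise the mandatory weight prompt first).
    """
    regions = regions_for(kb, drug_id)
    if not regions:
        return MatchOutcome(status="none")
    params = _known_parameters(patient, provided, kb, as_of)
    surviving = tuple(r for r in regions if _criteria_match_known(r.criteria, params))
    if len(surviving) == 1:
        return MatchOutcome(status="single", matched=surviving)
    if not surviving:
        return MatchOutcome(status="none")
    needed = _needed_parameters(surviving, params)
    if needed:
        return MatchOutcome(status="needs_input", matched=surviving, missing_inputs=needed)
    return MatchOutcome(status="multiple", matched=surviving)


# ---------------------------------------------------------------------------
# Dose computation
# ---------------------------------------------------------------------------


def apply_rounding(dose_mg: float, policy: RoundingPolicy) -> tuple:
    """Snap a dose to the nearest dispensable value within tolerance.

    Returns ``(rounded_dose_mg, was_rounded)``.  If the nearest table value
    lies farther than ``tolerance_fraction`` of the dose, no rounding occurs.
    A dose already in the table counts as rounded (zero distance).  Ties
    between two equidistant table values break toward the smaller value.
    """
    if not dose_mg > 0:
        raise ValueError("dose must be positive")
    if policy.kind == "none" or not policy.allowed_values_mg:
        return dose_mg, False
    nearest = min(policy.allowed_values_mg, key=lambda v: (abs(v - dose_mg), v))
    if abs(nearest - dose_mg) <= policy.tolerance_fraction * dose_mg:
        return nearest, True
    return dose_mg, False


def compute_dose(
    kb: KnowledgeBase,
    region: DosingRegion,
    dosing_weight: "WeightRecord | float",
) -> DoseProposal:
    """Raw weight-based (or flat) dose, then cap, then dispensable rounding."""
    if isinstance(dosing_weight, WeightRecord):
        weight_kg, record = dosing_weight.value_kg, dosing_weight
    else:
        weight_kg, record = float(dosing_weight), None
    if not weight_kg > 0:
        raise ValueError("dosing weight must be positive")
    rule = region.dose_rule
    raw = rule.amount_mg * weight_kg if rule.basis == "per_kg" else rule.amount_mg
    capped = raw
    was_capped = False
    if rule.max_single_dose_mg is not None and raw > rule.max_single_dose_mg:
        capped = rule.max_single_dose_mg
        was_capped = True
    rounded, was_rounded = apply_rounding(capped, kb.rounding_policy_for(region))
    return DoseProposal(
        region_id=region.region_id,
        raw_dose_mg=raw,
        capped_dose_mg=capped,
        rounded_dose_mg=rounded,
        route=rule.route,
        frequency=rule.frequency,
        was_capped=was_capped,
        was_rounded=was_rounded,
        weight_used=record,
        dose_count=rule.dose_count,
        prn=rule.prn,
    )


# ---------------------------------------------------------------------------
# Min/max bounds and the double-entry override
# ---------------------------------------------------------------------------


class BoundsUnavailable(Exception):
    """No dosing regions to derive bounds from (manual path, no check)."""


def bounds_for(kb: KnowledgeBase, drug_id: str, patient: Patient, as_of=None) -> tuple:
    """Min/max permitted single dose (mg) across the drug's dosing regions.

    Each region whose weight criterion admits the patient's current dosing
    weight is evaluated at that weight (caps applied); the extremes across
    those evaluations are the bounds.  Regions for other weight bands are
    excluded so that, e.g., a flat adolescent dose does not inflate the
    ceiling applied to a neonate.
    """
    regions = regions_for(kb, drug_id)
    if not regions:
        raise BoundsUnavailable(f"drug {drug_id!r} has no dosing regions")
    weight = patient.current_weight("dosing", as_of)
    if weight is None:
        raise MissingDosingWeight(f"patient {patient.patient_id!r} has no dosing weight")
    doses = []
    for region in regions:
        criterion = region.criteria.weight_kg
        if criterion is not None and not criterion.contains(weight.value_kg):
            continue
        rule = region.dose_rule
        dose = rule.amount_mg * weight.value_kg if rule.basis == "per_kg" else rule.amount_mg
        if rule.max_single_dose_mg is not None:
            dose = min(dose, rule.max_single_dose_mg)
        doses.append(dose)
    if not doses:
        raise BoundsUnavailable(
            f"no region of drug {drug_id!r} admits weight {weight.value_kg} kg"
        )
    return min(doses), max(doses)


def check_manual_dose(
    kb: KnowledgeBase, drug_id: str, patient: Patient, entered_dose_mg: float, as_of=None
) -> str:
    """Verdict on a manually entered dose: ``ok``, ``out_of_bounds``, or
    ``ok_no_check`` when no bounds can be derived.  Bounds are inclusive:
    a dose exactly at a sanctioned region dose must not alert."""
    if not entered_dose_mg > 0:
        raise ValueError("entered dose must be positive")
    try:
        low, high = bounds_for(kb, drug_id, patient, as_of)
    except BoundsUnavailable:
        return "ok_no_check"
    if entered_dose_mg < low or entered_dose_mg > high:
        return "out_of_bounds"
    return "ok"


def confirm_override(first_entry: str, second_entry: str) -> bool:
    """Double-entry confirmation of an aberrant dose.

    The user must retype the exact value: entries compare as
    whitespace-trimmed strings with no numeric coercion, so "1200.0" does not
    confirm "1200".
    """
    return str(first_entry).strip() == str(second_entry).strip()


# ---------------------------------------------------------------------------
# Order placement
# ---------------------------------------------------------------------------

_order_counter = 0


def _next_order_id() -> str:
    global _order_counter
    _order_counter += 1
    return f"ord-{_order_counter:06d}"


def place_order(
    kb: KnowledgeBase,
    patient: Patient,
    drug_id: str,
    *,
    proposal: Optional[DoseProposal] = None,
    manual_dose_mg: Optional[float] = None,
    inputs: Optional[dict] = None,
    allergy_overrides: int = 0,
    override_entries: Optional[tuple] = None,
    timestamp: Optional[datetime] = None,
    audit_log: Optional[AuditLog] = None,
    as_of: Optional[datetime] = None,
) -> tuple:
    """Accept an order from a region proposal or a manual dose.

    Gates, in order: the allergy gate (a drug on the patient's allergy list
    requires two explicit overrides), then — for manual doses judged out of
    bounds — the double-entry override protocol.  Every accepted manual order
    emits an :class:`AuditEntry` with a patient-parameter snapshot.

    Returns ``(OrderRecord, AuditEntry | None)``.
    """
    if (proposal is None) == (manual_dose_mg is None):
        raise ValueError("provide exactly one of proposal or manual_dose_mg")
    timestamp = timestamp or datetime.now()

    if drug_id in patient.allergies and allergy_overrides < 2:
        raise OrderBlocked(
            "allergy",
            f"{drug_id!r} is on the patient's allergy list; "
            f"two overrides required, got {allergy_overrides}",
        )

    audit = None
    if proposal is not None:
        order = OrderRecord(
            order_id=_next_order_id(),
            drug_id=drug_id,
            dose_mg=proposal.final_dose_mg,
            route=proposal.route,
            frequency=proposal.frequency,
            timestamp=timestamp,
            status="accepted",
            region_id=proposal.region_id,
            weight_used=proposal.weight_used,
            inputs=dict(inputs or {}),
        )
        return order, None

    verdict = check_manual_dose(kb, drug_id, patient, manual_dose_mg, as_of)
    annotation = None
    if verdict == "out_of_bounds":
        if override_entries is None or not confirm_override(*override_entries):
            raise OrderBlocked(
                "override",
                "manual dose is outside the permitted bounds and the exact "
                "value was not re-entered",
            )
        annotation = f"out-of-bounds dose confirmed by double entry: {override_entries[0]!r}"
        reason = "override"
    else:
        try:
            has_regions = bool(regions_for(kb, drug_id))
        except Exception:
            has_regions = False
        reason = "region_gap" if has_regions else "no_region"

    order = OrderRecord(
        order_id=_next_order_id(),
        drug_id=drug_id,
        dose_mg=float(manual_dose_mg),
        route=str((inputs or {}).get("route", "IV")),
        frequency=str((inputs or {}).get("frequency", "once")),
        timestamp=timestamp,
        status="accepted",
        manual=True,
        weight_used=patient.current_weight("dosing", as_of),
        override_annotation=annotation,
        inputs=dict(inputs or {}),
    )
    audit = AuditEntry(
        timestamp=timestamp,
        drug_id=drug_id,
        entered_dose_mg=float(manual_dose_mg),
        reason=reason,
        patient_snapshot=_patient_snapshot(patient, as_of),
    )
    if audit_log is not None:
        audit_log.append(audit)
    return order, audit
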