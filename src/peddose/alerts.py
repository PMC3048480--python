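"""Weight-integrity alerts, adult-content suppression, and advisor redirection.

Most pediatric dosing safeguards are undermined if the wrong weight is on
file, so weight entry is guarded by a suite of checks: a mandatory
dosing-weight prompt, growth-percentile screening against curve tables,
extreme weight-change and actual-vs-dosing variance popups, stale-parameter
tags, and weight-adjust reminders for orders dosed off superseded weights.
All checks are pure functions over patient state plus a per-care-area
:class:`~peddose.config.AlertConfig`; none mutates the patient.  Threshold
comparisons are strict (a change of exactly the threshold does not alert) to
keep the alert burden down — over-alerting is as ineffective as no alerting.

The same module hosts the two population guards used when one order-entry
system serves adults and children: suppression of adult dosing content for
pediatric patients (with an explicit exemption flag for content approved for
both populations) and redirection of adult-specific advisors to their
pediatric counterparts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional

from .config import AlertConfig
from .engine import MatchOutcome, OrderRecord, resolve
from .knowledge_base import KnowledgeBase, Medication
from .patients import (
    GrowthCurveSupportError,
    GrowthCurves,
    Patient,
    WeightRecord,
    classify_patient,
    growth_percentile,
)

logger = logging.getLogger(__name__)

ALERT_KINDS = (
    "missing_dosing_weight",
    "growth_percentile",
    "extreme_weight_change",
    "actual_dosing_variance",
    "stale_parameter",
    "weight_adjust_reminder",
    "suppression_notice",
    "redirection",
)

#: alert kinds delivered as the less invasive text tag rather than a popup
_TAG_KINDS = ("stale_parameter", "weight_adjust_reminder", "suppression_notice", "redirection")


@dataclass(frozen=True)
class Alert:
    kind: str
    message: str
    severity_channel: str = "popup"  # popup | tag
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ALERT_KINDS:
            raise ValueError(f"unknown alert kind {self.kind!r}")
        if self.severity_channel not in ("popup", "tag"):
            raise ValueError("severity_channel must be popup or tag")
        if self.kind == "stale_parameter" and self.severity_channel != "tag":
            raise ValueError("stale_parameter alerts are always tags")


def require_dosing_weight(patient: Patient, as_of: Optional[datetime] = None) -> Optional[Alert]:
    """Popup iff no current dosing weight is on file.

    No medication may be entered without a dosing weight; an actual weight
    does not satisfy the requirement (the two are distinct parameters).
    """
    if patient.current_weight("dosing", as_of) is not None:
        return None
    return Alert(
        kind="missing_dosing_weight",
        message=f"patient {patient.patient_id}: a dosing weight must be entered "
        "before any medication order",
        payload={"patient_id": patient.patient_id},
    )


def check_weight_entry(
    patient: Patient,
    new_weight: WeightRecord,
    curves: Optional[GrowthCurves],
    config: AlertConfig,
) -> list:
    """Screen a prospective weight entry; both checks may fire together.

    * growth-percentile popup when the value falls below ``percentile_low``
      or above ``percentile_high`` on the growth curves (skipped, with a
      logged notice, when the age or sex is outside curve support);
    * extreme-change popup when the relative change versus the previous
      record of the same kind strictly exceeds ``weight_change_fraction``.
    """
    if not new_weight.value_kg > 0:
        raise ValueError("weight must be positive")
    alerts = []

    if curves is not None and patient.sex is not None:
        try:
            pct = growth_percentile(
                new_weight.value_kg, patient.chronological_age_days, patient.sex, curves
            )
        except GrowthCurveSupportError as exc:
            logger.info("percentile check skipped for %s: %s", patient.patient_id, exc)
        else:
            if pct < config.percentile_low or pct > config.percentile_high:
                alerts.append(
                    Alert(
                        kind="growth_percentile",
                        message=(
                            f"weight {new_weight.value_kg} kg is at the "
                            f"{pct:.1f} percentile for age (warn band "
                            f"{config.percentile_low}-{config.percentile_high})"
                        ),
                        payload={
                            "percentile": pct,
                            "low": config.percentile_low,
                            "high": config.percentile_high,
                            "weight_kg": new_weight.value_kg,
                        },
                    )
                )

    previous = patient.current_weight(new_weight.kind, as_of=new_weight.timestamp)
    if previous is not None:
        change = abs(new_weight.value_kg - previous.value_kg) / previous.value_kg
        if change > config.weight_change_fraction:
            alerts.append(
                Alert(
                    kind="extreme_weight_change",
                    message=(
                        f"{new_weight.kind} weight changed {change:.0%} from the "
                        f"previously recorded {previous.value_kg} kg "
                        f"(threshold {config.weight_change_fraction:.0%})"
                    ),
                    payload={
                        "kind": new_weight.kind,
                        "previous_kg": previous.value_kg,
                        "new_kg": new_weight.value_kg,
                        "change_fraction": change,
                        "threshold": config.weight_change_fraction,
                    },
                )
            )
    return alerts


def check_variance(
    patient: Patient, config: AlertConfig, as_of: Optional[datetime] = None
) -> Optional[Alert]:
    """Popup when actual and dosing weight diverge beyond the variance
    threshold (relative to the actual weight).  Needs both weights on file;
    a missing weight is covered by the other rules."""
    actual = patient.current_weight("actual", as_of)
    dosing = patient.current_weight("dosing", as_of)
    if actual is None or dosing is None:
        return None
    variance = abs(dosing.value_kg - actual.value_kg) / actual.value_kg
    if variance <= config.actual_dosing_variance_fraction:
        return None
    return Alert(
        kind="actual_dosing_variance",
        message=(
            f"dosing weight {dosing.value_kg} kg differs from actual weight "
            f"{actual.value_kg} kg by {variance:.0%} "
            f"(threshold {config.actual_dosing_variance_fraction:.0%})"
        ),
        payload={
            "actual_kg": actual.value_kg,
            "dosing_kg": dosing.value_kg,
            "variance_fraction": variance,
            "threshold": config.actual_dosing_variance_fraction,
        },
    )


def stale_tags(patient: Patient, now: datetime, config: AlertConfig) -> list:
    """Text tags for weight parameters not updated within their cadence.

    A parameter with no record at all is *missing*, not stale — the
    mandatory-prompt rule covers that case.
    """
    tags = []
    for kind, limit_days in (
        ("actual", config.stale_days_actual),
        ("dosing", config.stale_days_dosing),
    ):
        record = patient.current_weight(kind, as_of=now)
        if record is None:
            continue
        age = now - record.timestamp
        if age > timedelta(days=limit_days):
            tags.append(
                Alert(
                    kind="stale_parameter",
                    severity_channel="tag",
                    message=(
                        f"{kind} weight last updated {age.days} days ago "
                        f"(expected within {limit_days})"
                    ),
                    payload={
                        "parameter": f"{kind}_weight",
                        "age_days": age.total_seconds() / 86400.0,
                        "limit_days": limit_days,
                    },
                )
            )
    return tags


def weight_adjust_reminders(
    orders: Iterable[OrderRecord], patient: Patient, as_of: Optional[datetime] = None
) -> list:
    """One reminder per live order dosed off a weight that has since changed."""
    current = patient.current_weight("dosing", as_of)
    reminders = []
    for order in orders:
        if order.weight_used is None or current is None:
            continue
        if (
            order.weight_used.timestamp == current.timestamp
            and order.weight_used.value_kg == current.value_kg
        ):
            continue
        reminders.append(
            Alert(
                kind="weight_adjust_reminder",
                severity_channel="tag",
                message=(
                    f"order {order.order_id} ({order.drug_id}) was dosed on "
                    f"{order.weight_used.value_kg} kg; the dosing weight is now "
                    f"{current.value_kg} kg — weight adjust the dose"
                ),
                payload={
                    "order_id": order.order_id,
                    "drug_id": order.drug_id,
                    "order_weight_kg": order.weight_used.value_kg,
                    "current_weight_kg": current.value_kg,
                },
            )
        )
    return reminders


def recheck_orders_on_weight_update(
    kb: KnowledgeBase,
    patient: Patient,
    orders: Iterable[OrderRecord],
    as_of: Optional[datetime] = None,
) -> list:
    """After a dosing-weight update, re-resolve every live region-based order.

    Returns ``(order, still_valid, outcome)`` triples; ``still_valid`` is
    False when the order's original region no longer matches the patient,
    with the fresh :class:`~peddose.engine.MatchOutcome` carrying whatever
    region should now be proposed.
    """
    results = []
    for order in orders:
        if order.region_id is None:
            continue
        outcome = resolve(kb, patient, order.drug_id, provided=order.inputs, as_of=as_of)
        still_valid = any(r.region_id == order.region_id for r in outcome.matched)
        results.append((order, still_valid, outcome))
    return results


@dataclass(frozen=True)
class ContentView:
    """A medication's guidance content as rendered for one patient."""

    drug_id: str
    adult_content: Optional[str]
    suppressed: bool
    notice: Optional[Alert] = None


def suppress_adult_content(
    patient: Patient, medication: Medication, as_of: Optional[datetime] = None
) -> ContentView:
    """Hide unapproved adult dosing content from pediatric patients.

    Base-form adult guidance is assumed *not* approved for pediatric use and
    is withheld whenever the patient meets the pediatric definition, unless
    the medication carries the both-populations exemption flag.
    """
    status = classify_patient(patient, as_of)
    if (
        medication.adult_content is None
        or not status.pediatric
        or medication.pediatric_approved_adult_content
    ):
        return ContentView(
            drug_id=medication.drug_id,
            adult_content=medication.adult_content,
            suppressed=False,
        )
    notice = Alert(
        kind="suppression_notice",
        severity_channel="tag",
        message=f"adult dosing content for {medication.drug_id} withheld for pediatric patient",
        payload={"drug_id": medication.drug_id, "patient_id": patient.patient_id},
    )
    return ContentView(
        drug_id=medication.drug_id, adult_content=None, suppressed=True, notice=notice
    )


def redirect_advisor(
    patient: Patient,
    advisor_id: str,
    advisor_pairs: dict,
    as_of: Optional[datetime] = None,
) -> str:
    """Reroute a pediatric patient's request for an adult advisor to the
    paired pediatric advisor; identity otherwise.  Idempotent: pediatric
    advisor ids are never themselves mapped."""
    status = classify_patient(patient, as_of)
    if not status.pediatric:
        return advisor_id
    target = advisor_pairs.get(advisor_id)
    if target is None:
        if advisor_id not in advisor_pairs.values():
            logger.info("advisor %r has no pediatric counterpart registered", advisor_id)
        return advisor_id
    return target
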