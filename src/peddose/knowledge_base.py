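"""Dosing-region knowledge base: types, loader, validator, and queries.

The unit of clinical knowledge is the *dosing region*: a constellation of
patient criteria (age, weight, care area, indication, renal status, order-set
context) mapped to one dose rule (per-kg or flat amount, route, frequency,
optional single-dose cap) and a dispensable-dose rounding policy.  A drug
carries as many regions as its clinical usage scenarios require.

A knowledge base is one structured-text (YAML) document with an explicit
format-version field.  The loader normalizes all masses to mg and all body
weights to kg, cross-links every reference, and fails loudly — naming the
offending record and field — on schema violations or dangling references.
``validate_kb`` additionally reports *content* problems (duplicate ids,
inverted intervals, criteria overlaps between regions of the same drug)
without raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from ._common import parse_mass_mg, years_to_days
from .config import AlertConfig

SUPPORTED_FORMAT_VERSIONS = ("1.0",)

RENAL_STATUSES = ("any", "impaired", "not_impaired")


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBLoadError(KBError):
    """Schema violation or dangling reference while loading a KB file."""


class NotInFormularyError(KBError):
    """A drug_id that does not exist in the knowledge base."""


class _AnyToken:
    """Explicit 'unconstrained' token for set-valued criteria.

    Kept distinct from an empty/absent set so that "criterion absent" can
    never be confused with "criterion unconstrained".
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ANY"

    def __contains__(self, item) -> bool:
        return True


ANY = _AnyToken()

CriterionSet = Union[_AnyToken, frozenset]


@dataclass(frozen=True)
class Interval:
    """A numeric interval with per-bound inclusivity; ``None`` = unbounded."""

    lower: Optional[float] = None
    upper: Optional[float] = None
    lower_inclusive: bool = True
    upper_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"inverted interval: lower {self.lower} > upper {self.upper}")

    def contains(self, x: float) -> bool:
        if self.lower is not None:
            if x < self.lower or (x == self.lower and not self.lower_inclusive):
                return False
        if self.upper is not None:
            if x > self.upper or (x == self.upper and not self.upper_inclusive):
                return False
        return True

    __contains__ = contains


@dataclass(frozen=True)
class DoseRule:
    """One region's dose prescription, normalized to mg (per dose)."""

    basis: str  # "per_kg" (mg per kg of dosing weight) or "flat"
    amount_mg: float
    route: str
    frequency: str
    max_single_dose_mg: Optional[float] = None
    dose_count: Optional[int] = None
    prn: bool = False

    def __post_init__(self) -> None:
        if self.basis not in ("per_kg", "flat"):
            raise ValueError(f"dose basis must be per_kg or flat, got {self.basis!r}")
        if not self.amount_mg > 0:
            raise ValueError("dose amount must be positive")
        if self.max_single_dose_mg is not None and not self.max_single_dose_mg > 0:
            raise ValueError("max_single_dose must be positive")
        if self.dose_count is not None and self.dose_count < 1:
            raise ValueError("dose_count must be >= 1")


@dataclass(frozen=True)
class CriteriaSet:
    """Patient criteria under which a dosing region applies.

    Intervals use canonical units (days for ages, kg for weight) and carry
    per-bound inclusivity so that boundary semantics such as "<8" vs "≥8" kg
    are preserved exactly as authored.
    """

    age_days: Optional[Interval] = None
    pca_days: Optional[Interval] = None  # post-conceptual age
    weight_kg: Optional[Interval] = None
    care_areas: CriterionSet = ANY
    indications: CriterionSet = ANY
    renal_status: str = "any"
    order_set_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.renal_status not in RENAL_STATUSES:
            raise ValueError(f"renal_status must be one of {RENAL_STATUSES}")


@dataclass(frozen=True)
class RoundingPolicy:
    """A dispensable-dose rounding table.

    ``allowed_values_mg`` lists the dispensable amounts; a computed dose is
    snapped to the nearest listed value only when that value lies within
    ``tolerance_fraction`` of the computation, otherwise no rounding occurs.
    """

    policy_id: str
    kind: str  # percent10 | percent5 | custom | none
    allowed_values_mg: tuple = ()
    tolerance_fraction: float = 0.10

    _KIND_TOLERANCE = {"percent10": 0.10, "percent5": 0.05}

    def __post_init__(self) -> None:
        if self.kind not in ("percent10", "percent5", "custom", "none"):
            raise ValueError(f"unknown rounding kind {self.kind!r}")
        if self.kind == "none":
            if self.allowed_values_mg:
                raise ValueError("kind=none must have an empty value table")
            return
        if not self.allowed_values_mg:
            raise ValueError(f"rounding table {self.policy_id!r} has no values")
        values = self.allowed_values_mg
        if any(v <= 0 for v in values):
            raise ValueError("rounding-table values must be positive")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("rounding-table values must be strictly increasing")
        if not 0.0 < self.tolerance_fraction <= 0.5:
            raise ValueError("tolerance_fraction must be in (0, 0.5]")


@dataclass(frozen=True)
class DosingRegion:
    region_id: str
    drug_id: str
    criteria: CriteriaSet
    dose_rule: DoseRule
    rounding_policy_id: str
    guidance_text: Optional[str] = None


@dataclass(frozen=True)
class Medication:
    drug_id: str
    name: str
    ahfs_class: Optional[str] = None
    adult_content: Optional[str] = None
    pediatric_approved_adult_content: bool = False
    nephrotoxic: bool = False
    region_ids: tuple = ()


@dataclass(frozen=True)
class CareArea:
    code: str
    name: str
    alert_config: AlertConfig


@dataclass
class KnowledgeBase:
    format_version: str
    medications: dict = field(default_factory=dict)  # drug_id -> Medication
    regions: dict = field(default_factory=dict)  # region_id -> DosingRegion
    rounding_policies: dict = field(default_factory=dict)  # id -> RoundingPolicy
    care_areas: dict = field(default_factory=dict)  # code -> CareArea
    order_set_indications: dict = field(default_factory=dict)  # order-set id -> indication
    advisor_pairs: dict = field(default_factory=dict)  # adult advisor id -> pediatric id
    growth_curve_fixture: Optional[str] = None

    def medication(self, drug_id: str) -> Medication:
        try:
            return self.medications[drug_id]
        except KeyError:
            raise NotInFormularyError(f"drug {drug_id!r} is not in the formulary") from None

    def rounding_policy_for(self, region: DosingRegion) -> RoundingPolicy:
        return self.rounding_policies[region.rounding_policy_id]

    def alert_config(self, care_area: str) -> AlertConfig:
        """The care area's configured thresholds, or baseline defaults."""
        area = self.care_areas.get(care_area)
        return area.alert_config if area is not None else AlertConfig(care_area=care_area)


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # duplicate_region | criteria_overlap | unit_anomaly | inverted_interval
    message: str
    region_ids: tuple = ()


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------


def _ctx(record: str, fld: str) -> str:
    return f"{record}: field {fld!r}"


def _require(mapping: dict, fld: str, record: str):
    if fld not in mapping or mapping[fld] is None:
        raise KBLoadError(f"{_ctx(record, fld)} is required")
    return mapping[fld]


def _parse_interval(raw, record: str, fld: str, scale=None) -> Optional[Interval]:
    if raw is None:
        return None
    if not isinstance(raw, dict):
        raise KBLoadError(f"{_ctx(record, fld)} must be a mapping with min/max bounds")
    known = {"min", "max", "min_inclusive", "max_inclusive", "unit"}
    unknown = set(raw) - known
    if unknown:
        raise KBLoadError(f"{_ctx(record, fld)} has unknown keys {sorted(unknown)}")
    factor = 1.0
    unit = raw.get("unit")
    if unit is not None:
        if scale is None or unit not in scale:
            raise KBLoadError(f"{_ctx(record, fld)}: unsupported unit {unit!r}")
        factor = scale[unit]
    lo = raw.get("min")
    hi = raw.get("max")
    try:
        return Interval(
            lower=None if lo is None else float(lo) * factor,
            upper=None if hi is None else float(hi) * factor,
            lower_inclusive=bool(raw.get("min_inclusive", True)),
            upper_inclusive=bool(raw.get("max_inclusive", True)),
        )
    except ValueError as exc:
        raise KBLoadError(f"{_ctx(record, fld)}: {exc}") from None


_AGE_UNIT_SCALE = {"days": 1.0, "years": years_to_days(1.0)}


def _parse_criterion_set(raw, record: str, fld: str) -> CriterionSet:
    if raw is None or (isinstance(raw, str) and raw.upper() == "ANY"):
        return ANY
    if not isinstance(raw, list) or not raw:
        raise KBLoadError(f"{_ctx(record, fld)} must be 'ANY' or a non-empty list")
    return frozenset(str(v) for v in raw)


def _parse_dose_rule(raw, record: str) -> DoseRule:
    if not isinstance(raw, dict):
        raise KBLoadError(f"{record}: 'dose' must be a mapping")
    basis = _require(raw, "basis", record)
    amount = _require(raw, "amount", record)
    cap = raw.get("max_single_dose")
    try:
        return DoseRule(
            basis=str(basis),
            amount_mg=parse_mass_mg(amount),
            route=str(_require(raw, "route", record)),
            frequency=str(_require(raw, "frequency", record)),
            max_single_dose_mg=None if cap is None else parse_mass_mg(cap),
            dose_count=None if raw.get("dose_count") is None else int(raw["dose_count"]),
            prn=bool(raw.get("prn", False)),
        )
    except ValueError as exc:
        raise KBLoadError(f"{record}: invalid dose rule: {exc}") from None


def load_kb(path) -> KnowledgeBase:
    """Load and cross-link a knowledge-base file.

    Raises :class:`KBLoadError` naming the offending record and field on any
    schema violation or dangling cross-reference.
    """
    path = Path(path)
    if not path.exists():
        raise KBLoadError(f"knowledge-base file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise KBLoadError(f"not valid YAML: {exc}") from None
    return parse_kb(doc)


def parse_kb(doc) -> KnowledgeBase:
    if not isinstance(doc, dict):
        raise KBLoadError("knowledge base document must be a mapping")
    version = _require(doc, "format_version", "document")
    if str(version) not in SUPPORTED_FORMAT_VERSIONS:
        raise KBLoadError(f"document: unsupported format_version {version!r}")
    kb = KnowledgeBase(format_version=str(version), growth_curve_fixture=doc.get("growth_curves"))

    for raw in doc.get("care_areas") or []:
        code = str(_require(raw, "code", "care_area"))
        overrides = raw.get("alerts") or {}
        try:
            cfg = AlertConfig(care_area=code, **overrides)
        except (TypeError, ValueError) as exc:
            raise KBLoadError(f"care_area {code!r}: bad alert config: {exc}") from None
        if code in kb.care_areas:
            raise KBLoadError(f"care_area {code!r}: duplicate code")
        kb.care_areas[code] = CareArea(code=code, name=str(raw.get("name", code)), alert_config=cfg)

    for raw in doc.get("rounding_policies") or []:
        pid = str(_require(raw, "id", "rounding_policy"))
        record = f"rounding_policy {pid!r}"
        kind = str(_require(raw, "kind", record))
        values = tuple(parse_mass_mg(v) for v in raw.get("allowed_values") or [])
        tol = raw.get("tolerance_fraction")
        if tol is None:
            tol = RoundingPolicy._KIND_TOLERANCE.get(kind, 0.10)
        try:
            policy = RoundingPolicy(
                policy_id=pid, kind=kind, allowed_values_mg=values, tolerance_fraction=float(tol)
            )
        except ValueError as exc:
            raise KBLoadError(f"{record}: {exc}") from None
        if pid in kb.rounding_policies:
            raise KBLoadError(f"{record}: duplicate id")
        kb.rounding_policies[pid] = policy

    for raw in doc.get("order_sets") or []:
        osid = str(_require(raw, "id", "order_set"))
        kb.order_set_indications[osid] = str(_require(raw, "indication", f"order_set {osid!r}"))

    for raw in doc.get("advisors") or []:
        adult = str(_require(raw, "adult", "advisor"))
        kb.advisor_pairs[adult] = str(_require(raw, "pediatric", f"advisor {adult!r}"))

    for raw in doc.get("medications") or []:
        drug_id = str(_require(raw, "drug_id", "medication"))
        record = f"medication {drug_id!r}"
        if drug_id in kb.medications:
            raise KBLoadError(f"{record}: duplicate drug_id")
        kb.medications[drug_id] = Medication(
            drug_id=drug_id,
            name=str(_require(raw, "name", record)),
            ahfs_class=raw.get("ahfs_class"),
            adult_content=raw.get("adult_content"),
            pediatric_approved_adult_content=bool(raw.get("pediatric_approved_adult_content", False)),
            nephrotoxic=bool(raw.get("nephrotoxic", False)),
        )

    for raw in doc.get("regions") or []:
        rid = str(_require(raw, "region_id", "region"))
        record = f"region {rid!r}"
        if rid in kb.regions:
            raise KBLoadError(f"{record}: duplicate region_id")
        drug_id = str(_require(raw, "drug_id", record))
        if drug_id not in kb.medications:
            raise KBLoadError(f"{record}: references unknown drug {drug_id!r}")
        crit_raw = raw.get("criteria") or {}
        renal = str(crit_raw.get("renal_status", "any"))
        try:
            criteria = CriteriaSet(
                age_days=_parse_interval(crit_raw.get("age_days"), record, "age_days", _AGE_UNIT_SCALE),
                pca_days=_parse_interval(crit_raw.get("pca_days"), record, "pca_days", _AGE_UNIT_SCALE),
                weight_kg=_parse_interval(crit_raw.get("weight_kg"), record, "weight_kg"),
                care_areas=_parse_criterion_set(crit_raw.get("care_areas"), record, "care_areas"),
                indications=_parse_criterion_set(crit_raw.get("indications"), record, "indications"),
                renal_status=renal,
                order_set_context=crit_raw.get("order_set"),
            )
        except ValueError as exc:
            raise KBLoadError(f"{record}: {exc}") from None
        if isinstance(criteria.care_areas, frozenset):
            unknown = criteria.care_areas - set(kb.care_areas)
            if kb.care_areas and unknown:
                raise KBLoadError(f"{record}: unknown care areas {sorted(unknown)}")
        if criteria.order_set_context is not None and criteria.order_set_context not in kb.order_set_indications:
            raise KBLoadError(f"{record}: references unknown order set {criteria.order_set_context!r}")
        policy_id = str(_require(raw, "rounding_policy", record))
        if policy_id not in kb.rounding_policies:
            raise KBLoadError(f"{record}: references unknown rounding policy {policy_id!r}")
        kb.regions[rid] = DosingRegion(
            region_id=rid,
            drug_id=drug_id,
            criteria=criteria,
            dose_rule=_parse_dose_rule(_require(raw, "dose", record), record),
            rounding_policy_id=policy_id,
            guidance_text=raw.get("guidance"),
        )

    # back-link region ids onto medications, preserving file order
    by_drug: dict = {d: [] for d in kb.medications}
    for region in kb.regions.values():
        by_drug[region.drug_id].append(region.region_id)
    kb.medications = {
        d: replace(m, region_ids=tuple(by_drug[d])) for d, m in kb.medications.items()
    }
    return kb


def write_kb(kb: KnowledgeBase, path) -> None:
    """Serialize a knowledge base back to its structured-text format."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(kb_to_document(kb), fh, sort_keys=False, allow_unicode=True)


def _interval_to_raw(iv: Optional[Interval]):
    if iv is None:
        return None
    raw: dict = {}
    if iv.lower is not None:
        raw["min"] = iv.lower
        if not iv.lower_inclusive:
            raw["min_inclusive"] = False
    if iv.upper is not None:
        raw["max"] = iv.upper
        if not iv.upper_inclusive:
            raw["max_inclusive"] = False
    return raw


def _set_to_raw(s: CriterionSet):
    return "ANY" if s is ANY else sorted(s)


def kb_to_document(kb: KnowledgeBase) -> dict:
    doc: dict = {"format_version": kb.format_version}
    if kb.growth_curve_fixture:
        doc["growth_curves"] = kb.growth_curve_fixture
    doc["care_areas"] = [
        {
            "code": a.code,
            "name": a.name,
            "alerts": {
                "weight_change_fraction": a.alert_config.weight_change_fraction,
                "actual_dosing_variance_fraction": a.alert_config.actual_dosing_variance_fraction,
                "stale_days_actual": a.alert_config.stale_days_actual,
                "stale_days_dosing": a.alert_config.stale_days_dosing,
                "percentile_low": a.alert_config.percentile_low,
                "percentile_high": a.alert_config.percentile_high,
            },
        }
        for a in kb.care_areas.values()
    ]
    doc["rounding_policies"] = [
        {
            "id": p.policy_id,
            "kind": p.kind,
            "tolerance_fraction": p.tolerance_fraction,
            "allowed_values": [f"{v} mg" for v in p.allowed_values_mg],
        }
        for p in kb.rounding_policies.values()
    ]
    doc["order_sets"] = [
        {"id": k, "indication": v} for k, v in kb.order_set_indications.items()
    ]
    doc["advisors"] = [{"adult": k, "pediatric": v} for k, v in kb.advisor_pairs.items()]
    doc["medications"] = [
        {
            "drug_id": m.drug_id,
            "name": m.name,
            "ahfs_class": m.ahfs_class,
            "adult_content": m.adult_content,
            "pediatric_approved_adult_content": m.pediatric_approved_adult_content,
            "nephrotoxic": m.nephrotoxic,
        }
        for m in kb.medications.values()
    ]
    doc["regions"] = []
    for r in kb.regions.values():
        crit: dict = {}
        for fld, iv in (
            ("age_days", r.criteria.age_days),
            ("pca_days", r.criteria.pca_days),
            ("weight_kg", r.criteria.weight_kg),
        ):
            raw = _interval_to_raw(iv)
            if raw is not None:
                crit[fld] = raw
        crit["care_areas"] = _set_to_raw(r.criteria.care_areas)
        crit["indications"] = _set_to_raw(r.criteria.indications)
        crit["renal_status"] = r.criteria.renal_status
        if r.criteria.order_set_context is not None:
            crit["order_set"] = r.criteria.order_set_context
        dose: dict = {
            "basis": r.dose_rule.basis,
            "amount": f"{r.dose_rule.amount_mg} mg",
            "route": r.dose_rule.route,
            "frequency": r.dose_rule.frequency,
        }
        if r.dose_rule.max_single_dose_mg is not None:
            dose["max_single_dose"] = f"{r.dose_rule.max_single_dose_mg} mg"
        if r.dose_rule.dose_count is not None:
            dose["dose_count"] = r.dose_rule.dose_count
        if r.dose_rule.prn:
            dose["prn"] = True
        entry = {
            "region_id": r.region_id,
            "drug_id": r.drug_id,
            "criteria": crit,
            "dose": dose,
            "rounding_policy": r.rounding_policy_id,
        }
        if r.guidance_text is not None:
            entry["guidance"] = r.guidance_text
        doc["regions"].append(entry)
    return doc


# ---------------------------------------------------------------------------
# Queries and content validation
# ---------------------------------------------------------------------------


def regions_for(kb: KnowledgeBase, drug_id: str) -> list:
    """All dosing regions for a drug, in authored order.

    An empty list means the drug is in the formulary but carries no pediatric
    regions — the signal to exit the advanced-dosing path and fall back to
    manual entry.  An unknown drug raises :class:`NotInFormularyError`.
    """
    med = kb.medication(drug_id)
    return [kb.regions[rid] for rid in med.region_ids]


# Grid used for brute-force overlap sampling: ages 0-18 y at a 5-day stride,
# weights 0.4-100 kg at 0.1 kg.  Adequate resolution at clinical KB scale.
_AGE_GRID = np.arange(0.0, years_to_days(18.0) + 5.0, 5.0)
_WEIGHT_GRID = np.arange(0.4, 100.0 + 0.05, 0.1)


def _interval_mask(iv: Optional[Interval], grid: np.ndarray) -> np.ndarray:
    if iv is None:
        return np.ones_like(grid, dtype=bool)
    mask = np.ones_like(grid, dtype=bool)
    if iv.lower is not None:
        mask &= grid > iv.lower if not iv.lower_inclusive else grid >= iv.lower
    if iv.upper is not None:
        mask &= grid < iv.upper if not iv.upper_inclusive else grid <= iv.upper
    return mask


def _sets_intersect(a: CriterionSet, b: CriterionSet) -> bool:
    if a is ANY or b is ANY:
        return True
    return bool(a & b)


def _renal_compatible(a: str, b: str) -> bool:
    return a == "any" or b == "any" or a == b


def _criteria_overlap(c1: CriteriaSet, c2: CriteriaSet) -> bool:
    """True if some synthetic parameter point satisfies both criteria sets."""
    if not _sets_intersect(c1.care_areas, c2.care_areas):
        return False
    if not _sets_intersect(c1.indications, c2.indications):
        return False
    if not _renal_compatible(c1.renal_status, c2.renal_status):
        return False
    # Axis-aligned intervals: a joint point exists iff each axis overlaps.
    for iv1, iv2, grid in (
        (c1.age_days, c2.age_days, _AGE_GRID),
        (c1.pca_days, c2.pca_days, _AGE_GRID),
        (c1.weight_kg, c2.weight_kg, _WEIGHT_GRID),
    ):
        if not np.any(_interval_mask(iv1, grid) & _interval_mask(iv2, grid)):
            return False
    return True


def validate_kb(kb: KnowledgeBase) -> list:
    """Report content issues; returns an empty list on a clean KB.

    Reports, never raises: unit anomalies (implausibly large doses or caps
    smaller than a flat dose), inverted intervals, duplicate criteria, and
    pairwise criteria overlaps between regions of the same drug.
    """
    issues: list = []
    by_drug: dict = {}
    for region in kb.regions.values():
        by_drug.setdefault(region.drug_id, []).append(region)
        rule = region.dose_rule
        if rule.amount_mg > 10_000:
            issues.append(
                ValidationIssue(
                    kind="unit_anomaly",
                    message=f"region {region.region_id!r}: dose amount {rule.amount_mg} mg "
                    "is implausibly large (possible g/mg confusion)",
                    region_ids=(region.region_id,),
                )
            )
        if (
            rule.max_single_dose_mg is not None
            and rule.basis == "flat"
            and rule.amount_mg > rule.max_single_dose_mg
        ):
            issues.append(
                ValidationIssue(
                    kind="unit_anomaly",
                    message=f"region {region.region_id!r}: flat dose exceeds its own cap",
                    region_ids=(region.region_id,),
                )
            )

    for drug_id, regions in by_drug.items():
        for i, r1 in enumerate(regions):
            for r2 in regions[i + 1 :]:
                if not _criteria_overlap(r1.criteria, r2.criteria):
                    continue
                duplicate = r1.criteria == r2.criteria
                issues.append(
                    ValidationIssue(
                        kind="duplicate_region" if duplicate else "criteria_overlap",
                        message=(
                            f"drug {drug_id!r}: regions {r1.region_id!r} and {r2.region_id!r} "
                            + ("have identical criteria" if duplicate else "overlap: some patient satisfies both")
                        ),
                        region_ids=(r1.region_id, r2.region_id),
                    )
                )
    return issues


def kb_stats(kb: KnowledgeBase) -> dict:
    """Simple content counts for scripting (drug and region totals)."""
    return {
        "medications": len(kb.medications),
        "regions": len(kb.regions),
        "rounding_policies": len(kb.rounding_policies),
        "care_areas": len(kb.care_areas),
    }
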