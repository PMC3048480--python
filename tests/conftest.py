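"""Shared fixtures and independent oracles for the test suite.

The random KB/patient generators draw interval bounds on a coarse lattice
(multiples of 50 days and 1 kg) so that grid-sampling overlap detectors at
different strides agree exactly with interval arithmetic.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from peddose import AlertConfig, Patient, WeightRecord
from peddose.knowledge_base import (
    ANY,
    CriteriaSet,
    DoseRule,
    DosingRegion,
    Interval,
    KnowledgeBase,
    Medication,
    RoundingPolicy,
)
from peddose.synthetic import load_fixture_curves, load_fixture_kb

T0 = datetime(2008, 3, 1, 8, 0)

CARE_CODES = ("general", "picu", "nicu", "bmt")
INDICATIONS = ("meningitis", "osteomyelitis", "sepsis")


@pytest.fixture(scope="session")
def kb():
    return load_fixture_kb()


@pytest.fixture(scope="session")
def curves():
    return load_fixture_curves()


def make_patient(
    age_days,
    care_area,
    dosing_kg=None,
    actual_kg=None,
    sex="M",
    pid="pt",
    renal=None,
    pca_days=None,
    allergies=(),
):
    patient = Patient(
        patient_id=pid,
        chronological_age_days=int(age_days),
        care_area=care_area,
        sex=sex,
        renal_impairment=renal,
        post_conceptual_age_days=pca_days,
        allergies=set(allergies),
    )
    if actual_kg is not None:
        patient.add_weight(WeightRecord(actual_kg, T0 - timedelta(hours=2), "actual", "physician"))
    if dosing_kg is not None:
        patient.add_weight(WeightRecord(dosing_kg, T0 - timedelta(hours=1), "dosing", "physician"))
    return patient


# ---------------------------------------------------------------------------
# Random knowledge bases and patients (for engine-vs-oracle equivalence)
# ---------------------------------------------------------------------------


def _random_interval(rng, lo, hi, step):
    """Interval with bounds on the lattice lo + k*step, possibly open-ended."""
    kind = rng.integers(4)
    if kind == 0:
        return None
    grid = np.arange(lo, hi + step / 2, step)
    a, b = sorted(rng.choice(grid, size=2, replace=True))
    iv = {
        "lower": float(a) if kind != 2 else None,
        "upper": float(b) if kind != 1 else None,
        "lower_inclusive": bool(rng.integers(2)),
        "upper_inclusive": bool(rng.integers(2)),
    }
    return Interval(**iv)


def _random_set(rng, universe):
    if rng.random() < 0.4:
        return ANY
    size = int(rng.integers(1, len(universe) + 1))
    return frozenset(rng.choice(universe, size=size, replace=False).tolist())


def random_kb(rng, max_regions=12) -> KnowledgeBase:
    kb = KnowledgeBase(format_version="1.0")
    kb.rounding_policies["p10"] = RoundingPolicy(
        policy_id="p10",
        kind="percent10",
        allowed_values_mg=tuple(float(v) for v in (10, 25, 50, 100, 250, 500, 1000, 2000)),
    )
    n_drugs = int(rng.integers(1, 3))
    n_regions = int(rng.integers(1, max_regions + 1))
    drugs = [f"drug{i}" for i in range(n_drugs)]
    for drug in drugs:
        kb.medications[drug] = Medication(drug_id=drug, name=drug.title())
    for i in range(n_regions):
        drug = drugs[int(rng.integers(n_drugs))]
        criteria = CriteriaSet(
            age_days=_random_interval(rng, 0, 6550, 50),
            pca_days=_random_interval(rng, 150, 400, 50) if rng.random() < 0.2 else None,
            weight_kg=_random_interval(rng, 1, 100, 1),
            care_areas=_random_set(rng, CARE_CODES),
            indications=_random_set(rng, INDICATIONS),
            renal_status=str(rng.choice(["any", "any", "impaired", "not_impaired"])),
        )
        rule = DoseRule(
            basis=str(rng.choice(["per_kg", "flat"])),
            amount_mg=float(rng.choice([10, 25, 50, 75, 100, 500, 1000])),
            route="IV",
            frequency="q8h",
            max_single_dose_mg=float(rng.choice([500, 1000, 2000])) if rng.random() < 0.3 else None,
        )
        rid = f"{drug}-r{i}"
        kb.regions[rid] = DosingRegion(
            region_id=rid, drug_id=drug, criteria=criteria, dose_rule=rule,
            rounding_policy_id="p10",
        )
    by_drug = {d: tuple(r.region_id for r in kb.regions.values() if r.drug_id == d) for d in drugs}
    from dataclasses import replace

    kb.medications = {d: replace(m, region_ids=by_drug[d]) for d, m in kb.medications.items()}
    return kb


def random_patient(rng) -> tuple:
    """Returns (patient, provided) with a random subset of prompts supplied."""
    patient = make_patient(
        age_days=int(rng.integers(0, 6500)),
        care_area=str(rng.choice(CARE_CODES)),
        dosing_kg=float(np.round(rng.uniform(0.5, 99.5), 1)),
        pid=f"rp{rng.integers(1e6)}",
        renal=str(rng.choice(["impaired", "not_impaired"])) if rng.random() < 0.4 else None,
        pca_days=None,
    )
    if rng.random() < 0.3:
        patient.post_conceptual_age_days = patient.chronological_age_days + int(rng.integers(180, 290))
    provided = {}
    if rng.random() < 0.5:
        provided["indication"] = str(rng.choice(INDICATIONS))
    return patient, provided


def naive_region_filter(kb, patient, drug_id, provided) -> frozenset:
    """Plain re-implementation of criteria filtering, written long-hand.

    Filters by every parameter whose value is known and ignores criteria on
    unknown parameters; serves as the independent oracle for resolve().
    """
    weight = patient.current_weight("dosing").value_kg
    age = patient.chronological_age_days
    indication = provided.get("indication")
    renal = patient.renal_impairment
    pca = patient.post_conceptual_age_days
    survivors = []
    for rid in kb.medications[drug_id].region_ids:
        region = kb.regions[rid]
        c = region.criteria
        ok = True
        for iv, value in ((c.age_days, age), (c.weight_kg, weight)):
            if iv is None:
                continue
            if iv.lower is not None:
                if value < iv.lower or (value == iv.lower and not iv.lower_inclusive):
                    ok = False
            if iv.upper is not None:
                if value > iv.upper or (value == iv.upper and not iv.upper_inclusive):
                    ok = False
        if c.pca_days is not None and pca is not None:
            iv = c.pca_days
            if iv.lower is not None:
                if pca < iv.lower or (pca == iv.lower and not iv.lower_inclusive):
                    ok = False
            if iv.upper is not None:
                if pca > iv.upper or (pca == iv.upper and not iv.upper_inclusive):
                    ok = False
        if c.care_areas is not ANY and patient.care_area not in c.care_areas:
            ok = False
        if indication is not None and c.indications is not ANY and indication not in c.indications:
            ok = False
        if renal is not None and c.renal_status != "any" and c.renal_status != renal:
            ok = False
        if ok:
            survivors.append(rid)
    return frozenset(survivors)


def brute_force_overlaps(kb) -> set:
    """Point-sampling overlap oracle over a joint (age, weight, care area,
    indication, renal) grid; independent of validate_kb's per-axis masking."""
    age_grid = np.arange(0.0, 6601.0, 25.0)
    weight_grid = np.arange(0.5, 100.51, 0.5)
    care_univ = set(CARE_CODES) | {"other_area"}
    ind_univ = set(INDICATIONS) | {"other_ind"}

    def joint_mask(c):
        ages = np.array([c.age_days.contains(a) if c.age_days else True for a in age_grid])
        weights = np.array([c.weight_kg.contains(w) if c.weight_kg else True for w in weight_grid])
        return np.outer(ages, weights)

    found = set()
    regions = list(kb.regions.values())
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1 :]:
            if r1.drug_id != r2.drug_id:
                continue
            hit = False
            for care in care_univ:
                for ind in ind_univ:
                    for renal in ("impaired", "not_impaired"):
                        c1, c2 = r1.criteria, r2.criteria
                        if care not in c1.care_areas or care not in c2.care_areas:
                            continue
                        if ind not in c1.indications or ind not in c2.indications:
                            continue
                        if c1.renal_status != "any" and c1.renal_status != renal:
                            continue
                        if c2.renal_status != "any" and c2.renal_status != renal:
                            continue
                        # pca axis: both unconstrained or overlapping on grid
                        if c1.pca_days or c2.pca_days:
                            pca_grid = np.arange(0.0, 7001.0, 25.0)
                            m1 = np.array(
                                [c1.pca_days.contains(p) if c1.pca_days else True for p in pca_grid]
                            )
                            m2 = np.array(
                                [c2.pca_days.contains(p) if c2.pca_days else True for p in pca_grid]
                            )
                            if not np.any(m1 & m2):
                                continue
                        if np.any(joint_mask(c1) & joint_mask(c2)):
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    break
            if hit:
                found.add(frozenset((r1.region_id, r2.region_id)))
    return found
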