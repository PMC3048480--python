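"""Resolution algorithm, dose computation, bounds, override, order placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peddose import (
    AuditLog,
    BoundsUnavailable,
    OrderBlocked,
    RoundingPolicy,
    apply_rounding,
    bounds_for,
    check_manual_dose,
    compute_dose,
    confirm_override,
    place_order,
    resolve,
)
from peddose.engine import MissingDosingWeight
from peddose.knowledge_base import parse_kb

from conftest import make_patient, naive_region_filter, random_kb, random_patient

YEAR = 365.25


class TestResolve:
    def test_nicu_neonate_meningitis_resolves_to_iv_im_region(self, kb):
        patient = make_patient(5, "nicu", dosing_kg=3.2)
        outcome = resolve(kb, patient, "ampicillin", {"indication": "meningitis"})
        assert outcome.status == "single"
        assert outcome.region.region_id == "amp-men-nicu-le7d"
        assert outcome.region.dose_rule.route == "IV/IM"

    def test_general_care_adolescent_under_27kg_gets_75_per_kg(self, kb):
        patient = make_patient(int(15 * YEAR), "general", dosing_kg=20.0)
        outcome = resolve(kb, patient, "ampicillin", {"indication": "meningitis"})
        assert outcome.status == "single"
        assert outcome.region.region_id == "amp-mo-gen-lt27kg"
        assert outcome.region.dose_rule.amount_mg == 75.0

    def test_unknown_indication_prompts_before_deciding(self, kb):
        patient = make_patient(5, "nicu", dosing_kg=3.2)
        outcome = resolve(kb, patient, "ampicillin")
        assert outcome.status == "needs_input"
        assert outcome.missing_inputs == ("indication",)

    def test_order_set_identity_injects_the_indication(self, kb):
        patient = make_patient(800, "picu", dosing_kg=12.0)
        outcome = resolve(kb, patient, "ampicillin", {"order_set": "liver_txp_postop_set"})
        assert outcome.status == "single"
        assert outcome.region.region_id == "amp-ltpost-lt20kg"

    def test_ambiguous_picu_neonate_routes_to_manual(self, kb):
        # the two PICU rows overlap for neonates of at least 8 kg, as authored
        patient = make_patient(20, "picu", dosing_kg=8.5)
        outcome = resolve(kb, patient, "ampicillin", {"indication": "meningitis"})
        assert outcome.status == "multiple"

    def test_missing_dosing_weight_demands_the_prompt_first(self, kb):
        patient = make_patient(5, "nicu", actual_kg=3.2)
        with pytest.raises(MissingDosingWeight):
            resolve(kb, patient, "ampicillin", {"indication": "meningitis"})

    def test_matches_naive_filter_on_random_kb_patient_pairs(self):
        """resolve() surviving set == long-hand criteria filter, 1000 pairs."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            kb = random_kb(rng)
            drug = str(rng.choice(sorted(kb.medications)))
            patient, provided = random_patient(rng)
            expected = naive_region_filter(kb, patient, drug, provided)
            outcome = resolve(kb, patient, drug, provided)
            assert frozenset(r.region_id for r in outcome.matched) == expected or (
                outcome.status in ("none",) and not expected
            )
            if len(expected) == 1:
                assert outcome.status == "single"


class TestComputeDose:
    def test_per_kg_dose_capped_at_one_gram(self, kb):
        region = kb.regions["amp-men-bmt-ge8kg"]
        proposal = compute_dose(kb, region, 12.0)
        assert proposal.raw_dose_mg == 1200.0
        assert proposal.capped_dose_mg == 1000.0 and proposal.was_capped

    def test_per_kg_dose_below_cap_unchanged(self, kb):
        proposal = compute_dose(kb, kb.regions["amp-men-bmt-ge8kg"], 4.0)
        assert proposal.capped_dose_mg == 400.0 and not proposal.was_capped

    def test_flat_rule_ignores_weight(self, kb):
        region = kb.regions["amp-mo-gen-ge27kg"]
        for weight in (27.0, 40.0, 80.0):
            assert compute_dose(kb, region, weight).final_dose_mg == 2000.0

    def test_nondecreasing_in_weight_and_never_exceeds_cap(self, kb):
        region = kb.regions["amp-men-bmt-ge8kg"]
        doses = [compute_dose(kb, region, w).capped_dose_mg for w in np.linspace(1, 40, 80)]
        assert all(b >= a for a, b in zip(doses, doses[1:]))
        assert max(doses) <= region.dose_rule.max_single_dose_mg


class TestApplyRounding:
    TABLE = RoundingPolicy(
        policy_id="t", kind="percent10",
        allowed_values_mg=(5.0, 10.0, 20.0, 30.0, 40.0, 45.0, 50.0, 60.0, 100.0, 200.0),
    )
    SPARSE = RoundingPolicy(policy_id="s", kind="percent10", allowed_values_mg=(100.0, 200.0))

    def test_rounds_to_nearest_value_within_ten_percent(self):
        assert apply_rounding(47.0, self.TABLE) == (45.0, True)

    def test_exact_table_value_counts_as_rounded(self):
        assert apply_rounding(50.0, self.TABLE) == (50.0, True)

    def test_no_rounding_outside_the_table_tolerance(self):
        assert apply_rounding(47.0, self.SPARSE) == (47.0, False)

    def test_tolerance_invariant_and_idempotence_on_random_doses(self):
        """|rounded - dose| <= tol*dose whenever rounded; rounding twice == once."""
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            values = np.unique(np.round(rng.uniform(1, 2000, size=rng.integers(1, 12)), 1))
            policy = RoundingPolicy(
                policy_id="r", kind="custom", allowed_values_mg=tuple(float(v) for v in values),
                tolerance_fraction=float(rng.choice([0.05, 0.1, 0.25])),
            )
            dose = float(np.round(rng.uniform(0.5, 2500), 2))
            rounded, was_rounded = apply_rounding(dose, policy)
            if was_rounded:
                assert abs(rounded - dose) <= policy.tolerance_fraction * dose + 1e-12
                assert rounded in policy.allowed_values_mg
            else:
                assert rounded == dose
            assert apply_rounding(rounded, policy) == (rounded, was_rounded or rounded in policy.allowed_values_mg)

    @given(dose=st.floats(0.5, 5000))
    @settings(max_examples=200, derandomize=True)
    def test_identity_policy_never_touches_the_dose(self, dose):
        policy = RoundingPolicy(policy_id="n", kind="none")
        assert apply_rounding(dose, policy) == (dose, False)


class TestBounds:
    def test_fixture_bounds_at_10kg_span_admissible_rules(self, kb):
        """Brute-force oracle: evaluate each region whose weight band admits
        10 kg; flat adolescent/liver rows (>=27, >=20 kg) are excluded."""
        patient = make_patient(800, "picu", dosing_kg=10.0)
        expected = []
        for region in kb.regions.values():
            band = region.criteria.weight_kg
            if band is not None and not band.contains(10.0):
                continue
            rule = region.dose_rule
            dose = rule.amount_mg * 10.0 if rule.basis == "per_kg" else rule.amount_mg
            if rule.max_single_dose_mg is not None:
                dose = min(dose, rule.max_single_dose_mg)
            expected.append(dose)
        low, high = bounds_for(kb, "ampicillin", patient)
        assert (low, high) == (min(expected), max(expected)) == (500.0, 1000.0)

    def test_every_admissible_region_dose_lies_within_bounds(self, kb):
        rng = np.random.default_rng(3)
        for _ in range(50):
            weight = float(np.round(rng.uniform(0.5, 80), 1))
            patient = make_patient(400, "picu", dosing_kg=weight)
            low, high = bounds_for(kb, "ampicillin", patient)
            for region in kb.regions.values():
                band = region.criteria.weight_kg
                if band is not None and not band.contains(weight):
                    continue
                dose = compute_dose(kb, region, weight).capped_dose_mg
                assert low <= dose <= high

    def test_single_region_drug_has_degenerate_bounds(self):
        rng = np.random.default_rng(9)
        kb = random_kb(rng, max_regions=1)
        drug = next(iter(kb.regions.values())).drug_id
        patient = make_patient(1000, "picu", dosing_kg=10.0)
        low, high = bounds_for(kb, drug, patient)
        assert low == high

    def test_drug_without_regions_has_no_bounds(self, kb):
        doc = {
            "format_version": "1.0",
            "medications": [{"drug_id": "bare", "name": "Bare"}],
        }
        bare_kb = parse_kb(doc)
        patient = make_patient(1000, "picu", dosing_kg=10.0)
        with pytest.raises(BoundsUnavailable):
            bounds_for(bare_kb, "bare", patient)
        assert check_manual_dose(bare_kb, "bare", patient, 500.0) == "ok_no_check"


class TestManualDoseCheck:
    def test_dose_exactly_at_max_is_ok_inclusive(self, kb):
        patient = make_patient(800, "picu", dosing_kg=10.0)
        _, high = bounds_for(kb, "ampicillin", patient)
        assert check_manual_dose(kb, "ampicillin", patient, high) == "ok"

    def test_tenfold_overdose_is_out_of_bounds(self, kb):
        patient = make_patient(800, "picu", dosing_kg=10.0)
        _, high = bounds_for(kb, "ampicillin", patient)
        assert check_manual_dose(kb, "ampicillin", patient, 10 * high) == "out_of_bounds"

    def test_dose_inside_the_band_is_ok(self, kb):
        patient = make_patient(800, "picu", dosing_kg=10.0)
        assert check_manual_dose(kb, "ampicillin", patient, 750.0) == "ok"


class TestConfirmOverride:
    @pytest.mark.parametrize(
        "first, second, accepted",
        [
            ("1200", "1200", True),
            (" 1200 ", "1200", True),  # whitespace-trimmed
            ("1200", "1200.0", False),  # numeric equality is not enough
            ("1200", "120", False),
        ],
    )
    def test_exact_reentry_contract(self, first, second, accepted):
        assert confirm_override(first, second) is accepted


class TestPlaceOrder:
    def test_region_proposal_produces_no_audit_entry(self, kb):
        patient = make_patient(5, "nicu", dosing_kg=3.2)
        outcome = resolve(kb, patient, "ampicillin", {"indication": "meningitis"})
        proposal = compute_dose(kb, outcome.region, patient.current_weight("dosing"))
        order, audit = place_order(kb, patient, "ampicillin", proposal=proposal)
        assert order.status == "accepted" and order.region_id == "amp-men-nicu-le7d"
        assert audit is None

    def test_manual_dose_in_region_gap_is_audited(self, kb):
        # a 2-year-old PICU patient falls in no meningitis region (rows end at 29 days)
        patient = make_patient(730, "picu", dosing_kg=12.0)
        log = AuditLog()
        order, audit = place_order(
            kb, patient, "ampicillin", manual_dose_mg=900.0, audit_log=log
        )
        assert order.manual and order.region_id is None
        assert audit is not None and audit.reason == "region_gap"
        assert log.entries == [audit]
        assert audit.patient_snapshot["dosing_weight_kg"] == 12.0

    def test_out_of_bounds_manual_dose_needs_double_entry(self, kb):
        patient = make_patient(730, "picu", dosing_kg=12.0)
        with pytest.raises(OrderBlocked) as excinfo:
            place_order(kb, patient, "ampicillin", manual_dose_mg=12_000.0)
        assert excinfo.value.reason == "override"
        order, audit = place_order(
            kb, patient, "ampicillin", manual_dose_mg=12_000.0,
            override_entries=("12000", "12000"),
        )
        assert audit.reason == "override" and order.override_annotation

    def test_allergy_gate_requires_two_overrides(self, kb):
        patient = make_patient(5, "nicu", dosing_kg=3.2, allergies=("ampicillin",))
        outcome = resolve(kb, patient, "ampicillin", {"indication": "meningitis"})
        proposal = compute_dose(kb, outcome.region, patient.current_weight("dosing"))
        with pytest.raises(OrderBlocked) as excinfo:
            place_order(kb, patient, "ampicillin", proposal=proposal, allergy_overrides=1)
        assert excinfo.value.reason == "allergy"
        order, _ = place_order(kb, patient, "ampicillin", proposal=proposal, allergy_overrides=2)
        assert order.status == "accepted"

    def test_every_accepted_manual_order_is_audited(self, kb):
        """Conservation of the audit trail across a batch of manual orders."""
        rng = np.random.default_rng(13)
        log = AuditLog()
        accepted = 0
        for _ in range(40):
            patient = make_patient(
                int(rng.integers(0, 6000)), "general",
                dosing_kg=float(np.round(rng.uniform(2, 60), 1)), pid=f"m{accepted}",
            )
            dose = float(np.round(rng.uniform(10, 4000), 0))
            try:
                _, audit = place_order(
                    kb, patient, "ampicillin", manual_dose_mg=dose, audit_log=log,
                    override_entries=(str(dose), str(dose)),
                )
            except OrderBlocked:
                continue
            accepted += 1
            assert audit is not None
        assert accepted == len(log.entries) > 0
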