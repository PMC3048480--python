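"""Weight-integrity alerts, suppression completeness, advisor redirection."""

import copy
from datetime import timedelta

import pytest

from peddose import (
    AlertConfig,
    WeightRecord,
    check_variance,
    check_weight_entry,
    compute_dose,
    place_order,
    recheck_orders_on_weight_update,
    redirect_advisor,
    require_dosing_weight,
    resolve,
    stale_tags,
    suppress_adult_content,
    weight_adjust_reminders,
)

from conftest import T0, make_patient

CONFIG = AlertConfig()
YEAR = 365.25


def _entry(value_kg, kind="actual", hours=0):
    return WeightRecord(value_kg, T0 + timedelta(hours=hours), kind, "physician")


class TestRequireDosingWeight:
    def test_patient_with_dosing_weight_passes(self):
        assert require_dosing_weight(make_patient(100, "nicu", dosing_kg=4.0)) is None

    def test_patient_without_any_weight_gets_popup(self):
        alert = require_dosing_weight(make_patient(100, "nicu"))
        assert alert.kind == "missing_dosing_weight" and alert.severity_channel == "popup"

    def test_actual_weight_does_not_satisfy_the_requirement(self):
        alert = require_dosing_weight(make_patient(100, "nicu", actual_kg=4.0))
        assert alert is not None


class TestCheckWeightEntry:
    def test_twelve_percent_jump_alerts(self, curves):
        patient = make_patient(400, "general", actual_kg=10.0)
        alerts = check_weight_entry(patient, _entry(11.2), curves, CONFIG)
        assert [a.kind for a in alerts] == ["extreme_weight_change"]
        assert alerts[0].payload["change_fraction"] == pytest.approx(0.12)

    def test_five_percent_drift_is_silent(self, curves):
        patient = make_patient(400, "general", actual_kg=10.0)
        assert check_weight_entry(patient, _entry(10.5), curves, CONFIG) == []

    def test_change_of_exactly_the_threshold_does_not_alert(self, curves):
        """Strict comparison: 10.0 -> 11.0 is exactly 10% and stays quiet."""
        patient = make_patient(400, "general", actual_kg=10.0)
        assert check_weight_entry(patient, _entry(11.0), curves, CONFIG) == []
        assert check_weight_entry(patient, _entry(11.01), curves, CONFIG) != []

    def test_pound_for_kilogram_miskey_is_caught(self, curves):
        patient = make_patient(400, "general", actual_kg=10.0)
        alerts = check_weight_entry(patient, _entry(22.05), curves, CONFIG)
        kinds = {a.kind for a in alerts}
        assert "extreme_weight_change" in kinds

    def test_percentile_and_change_alerts_can_cooccur(self, curves):
        patient = make_patient(400, "general", actual_kg=10.0)
        alerts = check_weight_entry(patient, _entry(30.0), curves, CONFIG)
        assert {a.kind for a in alerts} == {"extreme_weight_change", "growth_percentile"}

    def test_out_of_curve_support_skips_percentile_quietly(self, curves):
        adult = make_patient(int(30 * YEAR), "non_pediatric", actual_kg=70.0)
        assert check_weight_entry(adult, _entry(72.0), curves, CONFIG) == []

    def test_first_entry_has_no_change_baseline(self, curves):
        patient = make_patient(400, "general")
        median, _ = curves.median_sd(400, "M")
        assert check_weight_entry(patient, _entry(median), curves, CONFIG) == []

    def test_alerts_never_mutate_the_patient(self, curves):
        patient = make_patient(400, "general", actual_kg=10.0, dosing_kg=12.0)
        snapshot = copy.deepcopy(patient)
        check_weight_entry(patient, _entry(22.0), curves, CONFIG)
        check_variance(patient, CONFIG)
        stale_tags(patient, T0 + timedelta(days=5), CONFIG)
        assert patient == snapshot


class TestVariance:
    def test_small_discrepancy_is_silent(self):
        patient = make_patient(400, "general", actual_kg=10.0, dosing_kg=10.5)
        assert check_variance(patient, CONFIG) is None

    def test_twenty_percent_discrepancy_alerts(self):
        patient = make_patient(400, "general", actual_kg=10.0, dosing_kg=12.0)
        alert = check_variance(patient, CONFIG)
        assert alert.kind == "actual_dosing_variance"
        assert alert.payload["variance_fraction"] == pytest.approx(0.20)

    def test_equal_weights_and_missing_weight_are_silent(self):
        same = make_patient(400, "general", actual_kg=10.0, dosing_kg=10.0)
        assert check_variance(same, CONFIG) is None
        only_dosing = make_patient(400, "general", dosing_kg=10.0)
        assert check_variance(only_dosing, CONFIG) is None


class TestStaleTags:
    def test_fresh_weights_carry_no_tags(self):
        patient = make_patient(400, "general", actual_kg=10.0, dosing_kg=10.0)
        assert stale_tags(patient, T0, CONFIG) == []

    def test_actual_weight_three_days_old_is_tagged(self):
        patient = make_patient(400, "general", actual_kg=10.0)
        tags = stale_tags(patient, T0 + timedelta(days=3), CONFIG)
        assert len(tags) == 1
        assert tags[0].severity_channel == "tag"
        assert tags[0].payload["parameter"] == "actual_weight"

    def test_missing_record_is_not_stale(self):
        patient = make_patient(400, "general")
        assert stale_tags(patient, T0 + timedelta(days=30), CONFIG) == []


def _accepted_order(kb, patient, indication="meningitis"):
    outcome = resolve(kb, patient, "ampicillin", {"indication": indication})
    proposal = compute_dose(kb, outcome.region, patient.current_weight("dosing"))
    order, _ = place_order(
        kb, patient, "ampicillin", proposal=proposal, inputs={"indication": indication}
    )
    return order


class TestWeightAdjustReminders:
    def test_order_on_current_weight_needs_no_reminder(self, kb):
        patient = make_patient(5, "nicu", dosing_kg=3.2)
        order = _accepted_order(kb, patient)
        assert weight_adjust_reminders([order], patient) == []

    def test_weight_update_after_order_triggers_reminder(self, kb):
        patient = make_patient(5, "nicu", dosing_kg=3.2)
        order = _accepted_order(kb, patient)
        patient.add_weight(WeightRecord(3.6, T0 + timedelta(days=1), "dosing", "physician"))
        reminders = weight_adjust_reminders([order], patient)
        assert len(reminders) == 1
        assert reminders[0].payload["current_weight_kg"] == 3.6

    def test_one_reminder_per_stale_order(self, kb):
        patient = make_patient(5, "nicu", dosing_kg=3.2)
        orders = [_accepted_order(kb, patient) for _ in range(3)]
        patient.add_weight(WeightRecord(3.6, T0 + timedelta(days=1), "dosing", "physician"))
        assert len(weight_adjust_reminders(orders, patient)) == 3


class TestRecheckOnWeightUpdate:
    def test_crossing_the_8kg_boundary_invalidates_the_order(self, kb):
        patient = make_patient(20, "bmt", dosing_kg=7.5)
        order = _accepted_order(kb, patient)
        assert order.region_id == "amp-men-bmt-lt8kg"
        patient.add_weight(WeightRecord(8.5, T0 + timedelta(days=1), "dosing", "physician"))
        [(order_out, still_valid, outcome)] = recheck_orders_on_weight_update(kb, patient, [order])
        assert order_out is order and still_valid is False
        assert outcome.status == "single"
        assert outcome.region.region_id == "amp-men-bmt-ge8kg"

    def test_change_within_the_same_band_stays_valid(self, kb):
        patient = make_patient(20, "bmt", dosing_kg=5.0)
        order = _accepted_order(kb, patient)
        patient.add_weight(WeightRecord(5.4, T0 + timedelta(days=1), "dosing", "physician"))
        [(_, still_valid, _)] = recheck_orders_on_weight_update(kb, patient, [order])
        assert still_valid is True

    def test_flat_dose_region_unaffected_by_weight_change(self, kb):
        patient = make_patient(int(15 * YEAR), "general", dosing_kg=40.0)
        order = _accepted_order(kb, patient)
        assert order.region_id == "amp-mo-gen-ge27kg"
        patient.add_weight(WeightRecord(43.0, T0 + timedelta(days=1), "dosing", "physician"))
        [(_, still_valid, _)] = recheck_orders_on_weight_update(kb, patient, [order])
        assert still_valid is True


class TestSuppression:
    def test_pediatric_patient_never_sees_unapproved_adult_content(self, kb):
        child = make_patient(400, "general", dosing_kg=10.0)
        view = suppress_adult_content(child, kb.medication("ampicillin"))
        assert view.suppressed and view.adult_content is None
        assert view.notice.kind == "suppression_notice"

    def test_exempt_content_survives_for_pediatric_patients(self, kb):
        from dataclasses import replace

        med = replace(kb.medication("ampicillin"), pediatric_approved_adult_content=True)
        child = make_patient(400, "general", dosing_kg=10.0)
        view = suppress_adult_content(child, med)
        assert not view.suppressed and view.adult_content

    def test_adult_patient_sees_full_content(self, kb):
        adult = make_patient(int(30 * YEAR), "non_pediatric", dosing_kg=70.0)
        view = suppress_adult_content(adult, kb.medication("ampicillin"))
        assert not view.suppressed and view.adult_content

    def test_suppression_completeness_over_fixture_and_age_grid(self, kb):
        """No pediatric patient, at any fixture age/weight, is shown an
        unexempted adult content block."""
        from peddose import classify_pediatric

        for age_years in (0, 1, 5, 10, 13.9, 15, 17.9):
            for weight in (3.0, 10.0, 30.0, 44.9):
                patient = make_patient(int(age_years * YEAR), "general", dosing_kg=weight)
                if not classify_pediatric(patient.chronological_age_days, weight):
                    continue
                for med in kb.medications.values():
                    view = suppress_adult_content(patient, med)
                    if med.adult_content and not med.pediatric_approved_adult_content:
                        assert view.adult_content is None


class TestRedirection:
    def test_pediatric_request_for_adult_advisor_is_redirected(self, kb):
        child = make_patient(400, "general", dosing_kg=10.0)
        assert redirect_advisor(child, "adult_insulin", kb.advisor_pairs) == "pediatric_insulin"

    def test_adult_request_passes_through(self, kb):
        adult = make_patient(int(30 * YEAR), "non_pediatric", dosing_kg=70.0)
        assert redirect_advisor(adult, "adult_insulin", kb.advisor_pairs) == "adult_insulin"

    def test_redirection_is_idempotent(self, kb):
        child = make_patient(400, "general", dosing_kg=10.0)
        once = redirect_advisor(child, "adult_insulin", kb.advisor_pairs)
        assert redirect_advisor(child, once, kb.advisor_pairs) == once

    def test_unmapped_advisor_is_identity(self, kb):
        child = make_patient(400, "general", dosing_kg=10.0)
        assert redirect_advisor(child, "adult_heparin", kb.advisor_pairs) == "adult_heparin"
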