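"""Rule-engine behaviour: staging, diagnosis, dose resolution, warnings
and report assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from renalrx import (DoseRecommendation, Warning, band_for_gfr,
                     classify_ckd_stage, classify_t2dm_status, ddi_warnings,
                     generate_report, k_raising_warnings,
                     recommend_ckd_doses, recommend_t2dm_doses,
                     resolve_ckd_dose)
from renalrx.engine import DomainError, UnknownDrugError

from conftest import profile


class TestStaging:
    @pytest.mark.parametrize("gfr,stage", [
        (95, "G1"), (90, "G1"), (75, "G2"), (60, "G2"), (59.9, "G3a"),
        (45, "G3a"), (44.9, "G3b"), (30, "G3b"), (29.9, "G4"), (15, "G4"),
        (14.9, "G5"), (0.5, "G5"),
    ])
    def test_stage_boundaries(self, kb, gfr, stage):
        assert classify_ckd_stage(gfr, kb.staging_rules) == stage

    def test_nonpositive_gfr_rejected(self, kb):
        with pytest.raises(DomainError):
            classify_ckd_stage(0, kb.staging_rules)
        with pytest.raises(DomainError):
            classify_ckd_stage(-3, kb.staging_rules)

    def test_totality_against_interval_oracle(self, kb):
        """10^5 random eGFRs: exactly one stage, agreeing with a direct
        interval-membership oracle."""
        bounds = {"G1": (90, np.inf), "G2": (60, 90), "G3a": (45, 60),
                  "G3b": (30, 45), "G4": (15, 30), "G5": (0, 15)}
        rng = np.random.default_rng(2024)
        gfrs = rng.uniform(0.1, 200.0, size=100_000)
        for gfr in gfrs:
            stage = classify_ckd_stage(gfr, kb.staging_rules)
            oracle = [s for s, (lo, hi) in bounds.items() if lo <= gfr < hi]
            assert oracle == [stage]


class TestDiabetesStatus:
    @pytest.mark.parametrize("hba1c,status", [
        (5.0, "Normal"), (5.7, "Prediabetes"), (6.0, "Prediabetes"),
        (6.4, "Diabetes"), (7.0, "Diabetes"),
    ])
    def test_thresholds(self, hba1c, status):
        assert classify_t2dm_status(hba1c) == status

    def test_missing_hba1c_is_unknown_not_an_error(self):
        assert classify_t2dm_status(None) == "unknown"


class TestDoseResolution:
    def test_acarbose_mid_band_is_50mg_tid(self, kb):
        rec = resolve_ckd_dose(
            "Acarbose", profile(gfr=30, ckd="Yes", dialysis="No"), kb)
        assert isinstance(rec, DoseRecommendation)
        assert rec.band == "mid"
        assert rec.adjusted_maximum_dose == (50.0, 50.0)
        assert rec.display() == "50 mg t.i.d"

    def test_acebutolol_low_band_absolute_180_to_300mg(self, kb):
        rec = resolve_ckd_dose(
            "Acebutolol", profile(gfr=5, ckd="Yes", dialysis="No"), kb)
        assert isinstance(rec, DoseRecommendation)
        assert rec.resolved.kind == "absolute"
        assert (rec.resolved.amount_low, rec.resolved.amount_high) == \
            (180.0, 300.0)

    def test_amiloride_low_band_contraindicated(self, kb):
        result = resolve_ckd_dose(
            "Amiloride", profile(gfr=5, ckd="Yes", dialysis="No"), kb)
        assert isinstance(result, Warning)
        assert result.kind == "contraindicated"

    def test_glibornuride_no_data_warning(self, kb):
        result = resolve_ckd_dose(
            "Glibornuride", profile(gfr=30, ckd="Yes", dialysis="No"), kb)
        assert isinstance(result, Warning)
        assert result.kind == "no_data"

    def test_dialysis_yields_referral_not_dose(self, kb):
        result = resolve_ckd_dose(
            "Acarbose", profile(gfr=30, ckd="Yes", dialysis="Yes"), kb)
        assert isinstance(result, Warning)
        assert result.kind == "dialysis_referral"

    def test_missing_flags_fire_nothing(self, kb):
        assert resolve_ckd_dose("Acarbose", profile(gfr=30), kb) is None
        assert resolve_ckd_dose(
            "Acarbose", profile(gfr=30, ckd="Yes"), kb) is None  # dialysis unknown

    def test_unknown_drug_is_lookup_error(self, kb):
        with pytest.raises(UnknownDrugError):
            resolve_ckd_dose("NotADrug", profile(gfr=30, ckd="Yes",
                                                 dialysis="No"), kb)

    def test_range_fraction_reported_as_range(self, kb):
        # Benazepril low band is 25-50%, never collapsed to one number
        rec = resolve_ckd_dose(
            "Benazepril", profile(gfr=5, ckd="Yes", dialysis="No"), kb)
        assert rec.adjusted_maximum_dose == (20.0, 40.0)  # of 80 mg/day

    def test_fraction_of_nonnumeric_base_has_no_mg(self, kb):
        rec = resolve_ckd_dose(
            "Insulin", profile(gfr=30, ckd="Yes", dialysis="No"), kb)
        assert rec.adjusted_maximum_dose is None
        assert rec.resolved.fraction_low == 75

    def test_adjusted_dose_monotone_over_bands(self, kb):
        """For all-fraction rows with numeric doses, the adjusted maximum
        dose never increases as eGFR falls high -> mid -> low."""
        for entry in kb.dose_entries:
            kinds = {a.kind for a in entry.band_adjustments.values()}
            if kinds != {"fraction"} or not entry.maximum_dose.numeric:
                continue
            doses = []
            for gfr in (80.0, 30.0, 5.0):
                rec = resolve_ckd_dose(
                    entry.drug, profile(gfr=gfr, ckd="Yes", dialysis="No"), kb)
                doses.append(rec.adjusted_maximum_dose[1])
            assert doses == sorted(doses, reverse=True), entry.drug


class TestRecommendCkdDoses:
    def test_restricted_to_prescription(self, kb):
        p = profile(gfr=30, ckd="Yes", dialysis="No",
                    rx=["Acarbose", "Eprosartan"])
        recs = recommend_ckd_doses(p, kb)
        assert [r.drug for r in recs] == ["Acarbose", "Eprosartan"]
        eprosartan = recs[1]
        assert eprosartan.resolved.fraction_low == 100  # unchanged at mid band

    def test_no_ckd_flag_means_empty(self, kb):
        assert recommend_ckd_doses(
            profile(gfr=30, ckd="No", rx=["Acarbose"]), kb) == []

    def test_full_kb_mode_covers_every_dose_entry(self, kb):
        p = profile(gfr=30, ckd="Yes", dialysis="No")
        recs = recommend_ckd_doses(p, kb, restrict_to_prescription=False)
        assert len(recs) == len(kb.dose_entries)

    def test_unknown_prescription_drug_skipped(self, kb):
        p = profile(gfr=30, ckd="Yes", dialysis="No",
                    rx=["Acarbose", "NotADrug"])
        recs = recommend_ckd_doses(p, kb)
        assert [r.drug for r in recs] == ["Acarbose"]


class TestT2dmDoses:
    def test_mid_band_reduces_lispro_mix_by_25pct(self, kb):
        recs = recommend_t2dm_doses(profile(gfr=30, t2dm="Yes"), kb)
        assert [(r.drug, r.reduce_pct) for r in recs] == [("lispro_mix", 25.0)]

    def test_low_band_reduces_aspart_by_50pct(self, kb):
        recs = recommend_t2dm_doses(profile(gfr=5, t2dm="Yes"), kb)
        assert [(r.drug, r.reduce_pct) for r in recs] == \
            [("Aspart_NovoRapid", 50.0)]

    def test_no_t2dm_flag_means_empty(self, kb):
        assert recommend_t2dm_doses(profile(gfr=30), kb) == []
        assert recommend_t2dm_doses(profile(gfr=30, t2dm="No"), kb) == []


class TestDdiWarnings:
    def test_ara_with_ace_inhibitor_warns_once(self, kb):
        warnings = ddi_warnings({"Candesartan", "Benazepril"}, kb)
        assert [(w.kind, w.drugs) for w in warnings] == \
            [("ddi", ("Benazepril", "Candesartan"))]

    def test_diltiazem_with_beta_blocker(self, kb):
        warnings = ddi_warnings({"Diltiazem", "Metoprolol", "Amlodipine"}, kb)
        assert [w.drugs for w in warnings] == [("Diltiazem", "Metoprolol")]

    def test_singleton_and_noninteracting_sets_are_clean(self, kb):
        assert ddi_warnings({"Amlodipine"}, kb) == []
        assert ddi_warnings({"Amlodipine", "Felodipine", "Bumetanide"},
                            kb) == []

    def test_all_pairs_agree_with_closed_relation_oracle(self, kb):
        """Brute force over every 2-subset of the KB drug list."""
        from itertools import combinations
        pairs = kb.interaction_pairs()
        for a, b in combinations(sorted(kb.all_drugs()), 2):
            warnings = ddi_warnings({a, b}, kb)
            if frozenset((a, b)) in pairs:
                assert len(warnings) == 1
                assert warnings[0].drugs == tuple(sorted((a, b)))
            else:
                assert warnings == []

    def test_order_independence(self, kb):
        drugs = ["Ramipril", "Candesartan", "Verapamil", "Atenolol"]
        expected = ddi_warnings(drugs, kb)
        assert ddi_warnings(list(reversed(drugs)), kb) == expected
        assert ddi_warnings(frozenset(drugs), kb) == expected


class TestKRaisingWarnings:
    def test_spironolactone_warns(self, kb):
        warnings = k_raising_warnings({"Spironolactone"}, kb)
        assert [(w.kind, w.drugs) for w in warnings] == \
            [("k_raising", ("Spironolactone",))]

    def test_ace_inhibitor_warns_ccb_does_not(self, kb):
        warnings = k_raising_warnings({"Ramipril", "Amlodipine"}, kb)
        assert [w.drugs for w in warnings] == [("Ramipril",)]

    def test_non_k_raising_prescription_is_clean(self, kb):
        assert k_raising_warnings({"Amlodipine", "Diltiazem"}, kb) == []

    def test_every_member_of_flagged_classes_warns(self, kb):
        for drug in sorted(kb.k_raising_drugs()):
            assert len(k_raising_warnings({drug}, kb)) == 1


class TestGenerateReport:
    def test_worked_example_composition(self, kb, m001):
        report = generate_report(m001, kb)
        assert report.stage == "G3b"
        assert report.t2dm_status == "Diabetes"
        dose_by_drug = {r.drug: r for r in report.ckd_dose_recs}
        assert dose_by_drug["Acarbose"].display() == "50 mg t.i.d"
        kinds = [(w.kind, w.drugs) for w in report.warnings]
        assert ("ddi", ("Candesartan", "Ramipril")) in kinds
        assert ("k_raising", ("Candesartan",)) in kinds
        assert ("k_raising", ("Ramipril",)) in kinds
        assert len([k for k, _ in kinds if k == "ddi"]) == 1
        assert [(r.drug, r.reduce_pct) for r in report.t2dm_dose_recs] == \
            [("lispro_mix", 25.0)]

    def test_healthy_profile_yields_empty_recommendations(self, kb):
        report = generate_report(
            profile(gfr=95, ckd="No", t2dm="No", dialysis="No"), kb)
        assert report.stage == "G1"
        assert report.ckd_dose_recs == []
        assert report.t2dm_dose_recs == []
        assert report.warnings == []

    def test_determinism(self, kb, m001):
        a = generate_report(m001, kb).to_dict()
        b = generate_report(m001, kb).to_dict()
        assert a == b

    def test_flat_rows_shape(self, kb, m001):
        rows = generate_report(m001, kb).flat_rows()
        assert all(set(r) == {"patient_id", "item_type", "drug", "value",
                              "rule_id"} for r in rows)

    @settings(derandomize=True, max_examples=60)
    @given(gfr=st.floats(0.5, 150), ckd=st.sampled_from(["Yes", "No", None]),
           t2dm=st.sampled_from(["Yes", "No", None]),
           dialysis=st.sampled_from(["Yes", "No", None]))
    def test_safety_gating_property(self, kb, gfr, ckd, t2dm, dialysis):
        """No CKD dose is emitted unless has_ckd=Yes and has_dialysis=No;
        no diabetes dose unless has_t2dm=Yes."""
        report = generate_report(
            profile(gfr=gfr, ckd=ckd, t2dm=t2dm, dialysis=dialysis,
                    rx=["Acarbose", "Atenolol", "lispro_mix"]), kb)
        if ckd != "Yes" or dialysis != "No":
            assert report.ckd_dose_recs == []
        if t2dm != "Yes":
            assert report.t2dm_dose_recs == []
        if dialysis == "Yes" and ckd == "Yes":
            assert any(w.kind == "dialysis_referral" for w in report.warnings)
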