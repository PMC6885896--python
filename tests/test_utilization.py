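from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from mclclaims.utilization import (
    CATEGORIES,
    MONTH_DAYS,
    attribute_mcl_related,
    inflate_cents,
    inflate_cost,
    summarize_pppm,
)

IDX = date(2015, 1, 1)


# --- inflation -------------------------------------------------------------


def test_reference_year_amount_unchanged(codesets):
    assert inflate_cost(100.0, 2017, codesets.cpi) == 100.0
    assert inflate_cents(10000, 2017, codesets.cpi) == 10000


def test_inflation_multiplies_by_year_factor(codesets):
    f = codesets.cpi.factor(2014)
    assert inflate_cost(100.0, 2014, codesets.cpi) == pytest.approx(100 * f)


def test_reversal_amounts_keep_their_sign(codesets):
    pos = inflate_cents(10050, 2014, codesets.cpi)
    neg = inflate_cents(-10050, 2014, codesets.cpi)
    assert neg == -pos  # linearity under sign flip


def test_missing_year_raises(codesets):
    with pytest.raises(KeyError):
        inflate_cost(1.0, 1999, codesets.cpi)


# --- MCL attribution -------------------------------------------------------


def test_mcl_dx_at_any_position(codesets):
    claim = {"dx_codes": "I10;E119;C8319", "code": ""}
    assert attribute_mcl_related(claim, codesets)


def test_treatment_code_without_dx_is_mcl_related(codesets):
    assert attribute_mcl_related({"dx_codes": "", "code": "J9310"}, codesets)


def test_unrelated_pharmacy_claim_is_not(codesets):
    assert not attribute_mcl_related({"dx_codes": "", "code": "00591040501"}, codesets)


# --- PPPM summaries --------------------------------------------------------


def _cohort(followup_days):
    return pd.DataFrame([{
        "patient_id": "P1", "index_date": IDX,
        "censor_date": IDX + timedelta(days=followup_days - 1),
        "excluded_from_outcomes": False,
    }])


def _med_rows(rows):
    return pd.DataFrame(
        [{"claim_id": f"c{i}", "patient_id": "P1",
          "date": IDX + timedelta(days=r["day"]),
          "end_date": IDX + timedelta(days=r.get("end_day", r["day"])),
          "setting": r.get("setting", "office"), "code": r.get("code", ""),
          "dx_codes": r.get("dx", ""), "allowed_cents": r.get("cents", 0),
          "admission_id": r.get("adm", "")}
         for i, r in enumerate(rows)]
    )


EMPTY_RX = pd.DataFrame(
    columns=["claim_id", "patient_id", "date", "code", "days_supply",
             "quantity", "allowed_cents"]
)


def test_admission_pppm_and_los_arithmetic(codesets):
    followup = 609  # 20.0 months at 30.4375 days/month
    med = _med_rows([
        {"day": 10, "end_day": 14, "setting": "inpatient", "cents": 500000,
         "adm": "A1"},
    ])
    out = summarize_pppm(med, EMPTY_RX, _cohort(followup), codesets)
    rec = out.iloc[0]
    months = followup / MONTH_DAYS
    assert rec["followup_months"] == pytest.approx(20.0, rel=1e-3)
    assert rec["all_hospitalization_pppm"] == pytest.approx(0.05, rel=1e-3)
    assert rec["all_los_per_admission"] == 4.0  # discharge - admit
    inflated = inflate_cents(500000, 2015, codesets.cpi) / 100.0
    assert rec["all_hospitalization_cost_pppm"] == pytest.approx(inflated / months)


def test_overlapping_facility_claims_form_one_admission(codesets):
    med = _med_rows([
        {"day": 10, "end_day": 14, "setting": "inpatient", "cents": 100},
        {"day": 12, "end_day": 16, "setting": "inpatient", "cents": 100},
        {"day": 40, "end_day": 41, "setting": "inpatient", "cents": 100},
    ])
    out = summarize_pppm(med, EMPTY_RX, _cohort(609), codesets)
    rec = out.iloc[0]
    assert rec["all_hospitalization_pppm"] * rec["followup_months"] == pytest.approx(2)
    # merged admission spans day 10-16 (LOS 6), second admission LOS 1
    assert rec["all_los_per_admission"] == pytest.approx((6 + 1) / 2)


def test_patient_with_no_claims_has_zeros(codesets):
    out = summarize_pppm(_med_rows([]), EMPTY_RX, _cohort(100), codesets)
    rec = out.iloc[0]
    for cat in CATEGORIES:
        assert rec[f"all_{cat}_pppm"] == 0
        assert not rec[f"all_any_{cat}"]
    assert rec["all_total_cents"] == 0


def test_scope_nesting_and_exact_cents_partition(pipeline_200):
    res = pipeline_200
    df = res.pppm
    for cat in CATEGORIES:
        assert (df[f"mcl_{cat}_cents"] <= df[f"all_{cat}_cents"]).all()
        assert (df[f"mcl_{cat}_pppm"] <= df[f"all_{cat}_pppm"] + 1e-12).all()
    for scope in ("all", "mcl"):
        total = sum(df[f"{scope}_{cat}_cents"] for cat in CATEGORIES)
        assert (total == df[f"{scope}_total_cents"]).all()


def test_infused_drug_claims_count_as_pharmacy_not_office(codesets):
    med = _med_rows([
        {"day": 5, "code": "J9310", "cents": 100000},  # rituximab administration
        {"day": 6, "cents": 1000},                      # plain office visit
    ])
    out = summarize_pppm(med, EMPTY_RX, _cohort(100), codesets)
    rec = out.iloc[0]
    months = rec["followup_months"]
    assert rec["all_pharmacy_pppm"] == pytest.approx(1 / months)
    assert rec["all_office_pppm"] == pytest.approx(1 / months)
    assert rec["all_pharmacy_cents"] == inflate_cents(100000, 2015, codesets.cpi)


def test_pppm_invariant_under_followup_doubling(codesets):
    """Doubling follow-up with identical claim density leaves PPPM unchanged."""
    one_year = [{"day": d, "cents": 1000} for d in range(0, 360, 30)]
    two_years = one_year + [{"day": d + 365, "cents": 1000}
                            for d in range(0, 360, 30)]
    a = summarize_pppm(_med_rows(one_year), EMPTY_RX, _cohort(365), codesets).iloc[0]
    b = summarize_pppm(_med_rows(two_years), EMPTY_RX, _cohort(730), codesets).iloc[0]
    assert a["all_office_pppm"] == pytest.approx(b["all_office_pppm"], rel=0.01)
    assert a["all_total_cost_pppm"] == pytest.approx(b["all_total_cost_pppm"], rel=0.01)


def test_excluded_patients_dropped_from_outcomes(codesets):
    cohort = _cohort(100)
    cohort.loc[0, "excluded_from_outcomes"] = True
    out = summarize_pppm(_med_rows([{"day": 1}]), EMPTY_RX, cohort, codesets)
    assert len(out) == 0
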