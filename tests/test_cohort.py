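from datetime import date, timedelta

import pandas as pd
import pytest

from mclclaims.cohort import (
    CohortParams,
    apply_attrition,
    find_index_date,
    restrict_to_top_regimens,
)
from mclclaims.episodes import TreatmentClaimEvent, TreatmentEpisode


def ev(pid, d, agent="rituximab", route="infusion", supply=None, cortico=False):
    return TreatmentClaimEvent(patient_id=pid, date=d, agent=agent, route=route,
                               days_supply=supply, is_corticosteroid=cortico)


PARAMS = CohortParams()


# --- index date ------------------------------------------------------------


def test_index_is_first_treatment_inside_window():
    events = [ev("P1", date(2013, 10, 1)), ev("P1", date(2014, 1, 5))]
    assert find_index_date(events, PARAMS) == (date(2014, 1, 5), "rituximab")


def test_index_none_without_treatment():
    assert find_index_date([], PARAMS) is None
    cortico = [ev("P1", date(2015, 6, 1), "prednisone", "oral", 5, cortico=True)]
    assert find_index_date(cortico, PARAMS) is None


def test_single_infusion_indexes_itself():
    events = [ev("P1", date(2015, 6, 1))]
    assert find_index_date(events, PARAMS) == (date(2015, 6, 1), "rituximab")


# --- attrition cascade -----------------------------------------------------


def _tables(rows_enroll, rows_med):
    enrollment = pd.DataFrame(
        rows_enroll,
        columns=["patient_id", "start", "end", "birth_year", "gender", "region",
                 "plan_type"],
    )
    medical = pd.DataFrame(
        rows_med,
        columns=["claim_id", "patient_id", "date", "end_date", "setting", "code",
                 "dx_codes", "allowed_cents", "admission_id"],
    )
    pharmacy = pd.DataFrame(
        columns=["claim_id", "patient_id", "date", "code", "days_supply",
                 "quantity", "allowed_cents"]
    )
    return enrollment, medical, pharmacy


def _med(pid, d, dx="C8319", code=""):
    return [f"{pid}-{d}", pid, d, d, "office", code, dx, 0, ""]


def test_attrition_applies_enrollment_and_new_treatment_rules(codesets):
    # prior-treatment claims sit before the index window opens (Nov 2013), so
    # the later claim is the index and the baseline-treatment rule applies
    idx = date(2014, 6, 1)
    enroll = [
        # P1: clean — 24 months around index
        ["P1", idx - timedelta(days=730), idx + timedelta(days=730), 1960, "F", "South", "PPO"],
        # P2: only 11 months of pre-index enrollment
        ["P2", idx - timedelta(days=330), idx + timedelta(days=730), 1960, "M", "South", "PPO"],
        # P3: ibrutinib-indexed with baseline treatment -> retained but flagged
        ["P3", idx - timedelta(days=730), idx + timedelta(days=730), 1960, "M", "West", "HMO"],
        # P4: baseline-treated, non-ibrutinib index -> excluded
        ["P4", idx - timedelta(days=730), idx + timedelta(days=730), 1960, "F", "West", "PPO"],
    ]
    med = [_med(p, idx - timedelta(days=40)) for p in ("P1", "P2", "P3", "P4")]
    events = {
        "P1": [ev("P1", idx)],
        "P2": [ev("P2", idx)],
        "P3": [ev("P3", idx - timedelta(days=250), "bendamustine"),
               ev("P3", idx, "ibrutinib", "oral", 30)],
        "P4": [ev("P4", idx - timedelta(days=250), "bendamustine"),
               ev("P4", idx)],
    }
    enrollment, medical, pharmacy = _tables(enroll, med)
    cohort, ledger = apply_attrition(enrollment, medical, pharmacy, events,
                                     codesets, PARAMS)
    kept = set(cohort.patient_id)
    assert kept == {"P1", "P3"}
    rec = cohort.set_index("patient_id")
    assert not rec.loc["P1", "excluded_from_outcomes"]
    assert not rec.loc["P1", "prior_treated"]
    assert rec.loc["P3", "excluded_from_outcomes"]
    assert rec.loc["P3", "prior_treated"]
    counts = [e["n"] for e in ledger]
    assert counts == sorted(counts, reverse=True)  # monotone non-increasing
    stages = {e["stage"]: e["n"] for e in ledger}
    assert stages["12-month pre-index enrollment"] == 3  # P2 drops here
    assert stages["newly treated (ibrutinib exception)"] == 2  # P4 drops here


def test_minor_and_missing_mcl_dx_are_excluded(codesets):
    idx = date(2015, 6, 1)
    enroll = [
        ["P5", idx - timedelta(days=730), idx + timedelta(days=730), 2005, "F", "South", "PPO"],
        ["P6", idx - timedelta(days=730), idx + timedelta(days=730), 1960, "F", "South", "PPO"],
    ]
    med = [_med("P5", idx - timedelta(days=40)),
           _med("P6", idx - timedelta(days=40), dx="I10")]  # no MCL dx
    events = {"P5": [ev("P5", idx)], "P6": [ev("P6", idx)]}
    enrollment, medical, pharmacy = _tables(enroll, med)
    cohort, ledger = apply_attrition(enrollment, medical, pharmacy, events,
                                     codesets, PARAMS)
    assert len(cohort) == 0


def test_overlapping_enrollment_spans_raise(codesets):
    idx = date(2015, 6, 1)
    enroll = [
        ["P1", idx - timedelta(days=730), idx + timedelta(days=10), 1960, "F", "South", "PPO"],
        ["P1", idx - timedelta(days=5), idx + timedelta(days=730), 1960, "F", "South", "PPO"],
    ]
    med = [_med("P1", idx - timedelta(days=40))]
    events = {"P1": [ev("P1", idx)]}
    enrollment, medical, pharmacy = _tables(enroll, med)
    with pytest.raises(ValueError, match="overlapping"):
        apply_attrition(enrollment, medical, pharmacy, events, codesets, PARAMS)


def test_followup_runs_to_enrollment_or_study_end(codesets):
    idx = date(2017, 12, 1)
    enroll = [["P1", idx - timedelta(days=730), date(2019, 6, 30), 1960, "F",
               "South", "PPO"]]
    med = [_med("P1", idx - timedelta(days=40))]
    events = {"P1": [ev("P1", idx)]}
    enrollment, medical, pharmacy = _tables(enroll, med)
    cohort, _ = apply_attrition(enrollment, medical, pharmacy, events,
                                codesets, PARAMS)
    assert cohort.loc[0, "censor_date"] == PARAMS.study_end  # clipped


# --- top-regimen restriction ----------------------------------------------


def _episode(pid, label, line=1, start=date(2015, 1, 1)):
    return TreatmentEpisode(
        patient_id=pid, start=start, end=start + timedelta(days=100),
        regimen=frozenset({"x"}), end_reason="censored", line=line, label=label,
    )


def _cohort_frame(pids):
    return pd.DataFrame({
        "patient_id": pids,
        "excluded_from_outcomes": [False] * len(pids),
    })


def test_top_k_equal_to_universe_keeps_everyone():
    eps = {"P1": [_episode("P1", "A")], "P2": [_episode("P2", "B")]}
    cohort = _cohort_frame(["P1", "P2"])
    analytic, top, _ = restrict_to_top_regimens(cohort, eps, k=2)
    assert set(analytic.patient_id) == {"P1", "P2"}
    assert set(top) == {"A", "B"}


def test_retained_fraction_matches_counting_oracle():
    # 7 of 10 patients receive a top-2 regimen somewhere in their sequence
    eps = {}
    for i in range(5):
        eps[f"A{i}"] = [_episode(f"A{i}", "A")]
    for i in range(2):
        eps[f"B{i}"] = [_episode(f"B{i}", "rare"), _episode(f"B{i}", "B", line=2)]
    for i in range(3):
        eps[f"C{i}"] = [_episode(f"C{i}", f"solo{i}")]
    cohort = _cohort_frame(sorted(eps))
    analytic, top, ledger = restrict_to_top_regimens(cohort, eps, k=2)
    assert top == ["A", "B"]
    assert len(analytic) == 7
    assert ledger[0]["n"] == 7


def test_later_line_rituximab_counts_toward_monotherapy_ranking():
    eps = {
        "P1": [_episode("P1", "rituximab-mono")],
        "P2": [_episode("P2", "Z"),
               _episode("P2", "rituximab-maintenance-or-mono", line=2)],
        "P3": [_episode("P3", "Y")],
    }
    cohort = _cohort_frame(["P1", "P2", "P3"])
    _, top, _ = restrict_to_top_regimens(cohort, eps, k=1)
    assert top == ["rituximab-mono"]


def test_k_below_one_rejected():
    with pytest.raises(ValueError):
        restrict_to_top_regimens(_cohort_frame(["P1"]), {}, k=0)
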