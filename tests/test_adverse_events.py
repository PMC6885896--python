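from datetime import date, timedelta

import pandas as pd
import pytest

from mclclaims.adverse_events import (
    IncidentAE,
    ae_table_by_regimen,
    assign_burden_strata,
    detect_incident_aes,
    stratum_for_count,
)
from mclclaims.episodes import TreatmentEpisode

D0 = date(2015, 1, 1)


def _episode(pid, start_day, end_day, line=1, label="R-CHOP", reportable=True):
    return TreatmentEpisode(
        patient_id=pid, start=D0 + timedelta(days=start_day),
        end=D0 + timedelta(days=end_day), regimen=frozenset({"x"}),
        end_reason="censored", line=line, label=label, ae_reportable=reportable,
    )


def _med(rows):
    return pd.DataFrame(
        [
            {"claim_id": f"c{i}", "patient_id": pid,
             "date": D0 + timedelta(days=day),
             "end_date": D0 + timedelta(days=day), "setting": "office",
             "code": "", "dx_codes": dx, "allowed_cents": 0, "admission_id": ""}
            for i, (pid, day, dx) in enumerate(rows)
        ]
    )


def test_in_episode_claim_with_no_history_is_incident(codesets):
    med = _med([("P1", 30, "D649")])  # anemia during episode
    eps = {"P1": [_episode("P1", 0, 100)]}
    out = detect_incident_aes(med, eps, codesets)
    assert [(a.ae, a.line) for a in out] == [("anemia", 1)]
    assert out[0].date == D0 + timedelta(days=30)


def test_baseline_claim_blocks_incidence(codesets):
    med = _med([("P1", -200, "D649"), ("P1", 30, "D649")])
    eps = {"P1": [_episode("P1", 0, 100)]}
    assert detect_incident_aes(med, eps, codesets) == []


def test_claim_in_earlier_episode_blocks_later_episode(codesets):
    med = _med([("P1", 30, "D649"), ("P1", 230, "D649")])
    eps = {"P1": [_episode("P1", 0, 100), _episode("P1", 200, 300, line=2)]}
    out = detect_incident_aes(med, eps, codesets)
    assert [(a.ae, a.line) for a in out] == [("anemia", 1)]


def test_claim_between_episodes_is_not_attributed(codesets):
    med = _med([("P1", 150, "D649")])  # falls in the gap between episodes
    eps = {"P1": [_episode("P1", 0, 100), _episode("P1", 200, 300, line=2)]}
    assert detect_incident_aes(med, eps, codesets) == []


def test_no_ae_claims_gives_empty_list(codesets):
    med = _med([("P1", 30, "Z0000")])
    eps = {"P1": [_episode("P1", 0, 100)]}
    assert detect_incident_aes(med, eps, codesets) == []


def test_baseline_lookback_variant_forgets_old_history(codesets):
    med = _med([("P1", -400, "D649"), ("P1", 30, "D649")])
    eps = {"P1": [_episode("P1", 0, 100)]}
    assert detect_incident_aes(med, eps, codesets, lookback="all") == []
    got = detect_incident_aes(med, eps, codesets, lookback="baseline")
    assert [a.ae for a in got] == ["anemia"]


def test_excluded_patients_contribute_no_aes(codesets):
    med = _med([("P1", 30, "D649")])
    eps = {"P1": [_episode("P1", 0, 100)]}
    assert detect_incident_aes(med, eps, codesets, excluded_patients={"P1"}) == []


@pytest.mark.parametrize(
    "days,expected",
    [((10,), 0), ((10, 16), 0), ((10, 17), 1), ((10, 13, 40), 1)],
)
def test_secondary_malignancy_two_claim_rule(codesets, days, expected):
    """One claim never counts; two same-cancer claims need >= 7 days between."""
    med = _med([("P1", d, "C7801") for d in days])
    eps = {"P1": [_episode("P1", 0, 100)]}
    out = detect_incident_aes(med, eps, codesets)
    assert len(out) == expected
    if expected:
        assert out[0].ae == "secondary_malignancy"
        assert out[0].date == D0 + timedelta(days=min(days))


def test_secondary_malignancy_needs_same_cancer_family(codesets):
    med = _med([("P1", 10, "C7801"), ("P1", 40, "C7902")])
    eps = {"P1": [_episode("P1", 0, 100)]}
    assert detect_incident_aes(med, eps, codesets) == []
    # exact-code granularity is stricter still
    med2 = _med([("P1", 10, "C7801"), ("P1", 40, "C7809")])
    assert detect_incident_aes(med2, eps, codesets, same_cancer="exact") == []
    assert len(detect_incident_aes(med2, eps, codesets, same_cancer="family")) == 1


def test_excluded_family_codes_never_count(codesets):
    med = _med([("P1", 10, "C9600"), ("P1", 40, "C9600")])
    eps = {"P1": [_episode("P1", 0, 100)]}
    assert detect_incident_aes(med, eps, codesets) == []


def test_prior_single_claim_blocks_malignancy_family(codesets):
    med = _med([("P1", -100, "C7805"), ("P1", 10, "C7801"), ("P1", 40, "C7801")])
    eps = {"P1": [_episode("P1", 0, 100)]}
    assert detect_incident_aes(med, eps, codesets) == []


def test_incidence_monotone_in_history(codesets):
    """Adding any pre-episode claim can only remove incident calls."""
    med = _med([("P1", 30, "D649"), ("P1", 40, "D70"), ("P1", 50, "I10")])
    eps = {"P1": [_episode("P1", 0, 100)]}
    base = {a.ae for a in detect_incident_aes(med, eps, codesets)}
    for dx in ("D649", "D70", "I10", "R58", "Z0000"):
        med2 = pd.concat([med, _med([("P1", -50, dx)])], ignore_index=True)
        got = {a.ae for a in detect_incident_aes(med2, eps, codesets)}
        assert got <= base


# --- burden strata ---------------------------------------------------------


@pytest.mark.parametrize("n,s", [(0, "0"), (1, "1-2"), (2, "1-2"), (3, "3-5"),
                                 (5, "3-5"), (6, "6+"), (9, "6+")])
def test_stratum_boundaries(n, s):
    assert stratum_for_count(n) == s


def test_burden_counts_distinct_categories_not_claims(codesets):
    # two unique AEs mentioned in many claims -> count 2
    rows = [("P1", 30 + i, "D649") for i in range(5)]
    rows += [("P1", 40 + i, "D70") for i in range(5)]
    med = _med(rows)
    eps = {"P1": [_episode("P1", 0, 100)]}
    aes = detect_incident_aes(med, eps, codesets)
    burden = assign_burden_strata(aes, ["P1", "P2"])
    rec = burden.set_index("patient_id")
    assert rec.loc["P1", "ae_count"] == 2 and rec.loc["P1", "stratum"] == "1-2"
    assert rec.loc["P2", "ae_count"] == 0 and rec.loc["P2", "stratum"] == "0"


def test_strata_partition_the_cohort(pipeline_200):
    res = pipeline_200
    assert res.burden["stratum"].isin(["0", "1-2", "3-5", "6+"]).all()
    analyzed = set(res.cohort.loc[~res.cohort.excluded_from_outcomes.astype(bool),
                                  "patient_id"])
    analyzed &= set(p for p, eps in res.episodes_by_patient.items())
    assert set(res.burden.patient_id) <= set(res.cohort.patient_id)
    assert res.burden["patient_id"].is_unique


# --- regimen table ---------------------------------------------------------


def test_ae_table_counts_match_flat_recount(pipeline_200):
    res = pipeline_200
    tab = res.ae_table
    excluded = set(res.cohort.loc[res.cohort.excluded_from_outcomes.astype(bool),
                                  "patient_id"])
    for reg in tab["regimen"].unique():
        denom_pids = {
            pid for pid, eps in res.episodes_by_patient.items()
            if pid not in excluded and any(
                e.label == reg and e.ae_reportable for e in eps
            )
        }
        sub = tab[tab.regimen == reg].set_index("measure")
        assert sub.loc["patients", "n"] == len(denom_pids)
        recount = {
            pid for a in res.incident_aes
            if a.regimen_label == reg and a.patient_id in denom_pids
            for pid in [a.patient_id]
        }
        assert sub.loc["ge1_ae", "n"] == len(recount)
        assert sub.loc["no_ae", "n"] + sub.loc["ge1_ae", "n"] == len(denom_pids)


def test_ae_table_never_reports_later_line_rituximab(pipeline_200):
    assert "rituximab-maintenance-or-mono" not in set(
        pipeline_200.ae_table["regimen"]
    )


def test_every_patient_one_ae_gives_100_percent():
    aes = [IncidentAE("P1", "anemia", D0, 1, "B-R"),
           IncidentAE("P2", "diarrhea", D0, 1, "B-R")]
    eps = {"P1": [_episode("P1", 0, 100, label="B-R")],
           "P2": [_episode("P2", 0, 100, label="B-R")]}
    tab = ae_table_by_regimen(aes, eps).set_index("measure")
    assert tab.loc["ge1_ae", "pct"] == 100.0
    assert tab.loc["no_ae", "n"] == 0
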