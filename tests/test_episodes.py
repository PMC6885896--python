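from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from mclclaims.episodes import (
    EpisodeParams,
    TreatmentClaimEvent,
    assign_lines,
    build_episodes,
    coverage_gap,
    form_regimen,
    regimen_label,
)
from oracle import brute_force_episodes

D0 = date(2015, 1, 1)


def ev(day, agent, route="infusion", supply=None, cortico=False):
    return TreatmentClaimEvent(
        patient_id="P1", date=D0 + timedelta(days=day), agent=agent, route=route,
        days_supply=supply, is_corticosteroid=cortico,
    )


def days(d: date) -> int:
    return (d - D0).days


# --- regimen formation -----------------------------------------------------


def test_regimen_is_agent_union_in_window_excluding_corticosteroids():
    events = [
        ev(0, "rituximab"),
        ev(1, "cyclophosphamide"), ev(1, "doxorubicin"), ev(1, "vincristine"),
        ev(1, "prednisone", route="oral", supply=5, cortico=True),
    ]
    regimen, cortico = form_regimen(events, D0)
    assert regimen == frozenset(
        {"rituximab", "cyclophosphamide", "doxorubicin", "vincristine"}
    )
    assert cortico
    assert regimen_label(regimen) == "R-CHOP"


def test_window_boundary_day_34_in_day_35_out():
    inside = [ev(0, "rituximab"), ev(34, "bendamustine")]
    outside = [ev(0, "rituximab"), ev(35, "bendamustine")]
    assert form_regimen(inside, D0)[0] == frozenset({"rituximab", "bendamustine"})
    assert form_regimen(outside, D0)[0] == frozenset({"rituximab"})
    # day 36 even more clearly starts change evaluation
    assert form_regimen([ev(0, "rituximab"), ev(36, "bendamustine")], D0)[0] == \
        frozenset({"rituximab"})


def test_single_agent_regimen():
    regimen, cortico = form_regimen([ev(0, "ibrutinib", route="oral", supply=30)], D0)
    assert regimen == frozenset({"ibrutinib"}) and not cortico


def test_form_regimen_requires_event_at_start():
    with pytest.raises(ValueError):
        form_regimen([ev(5, "rituximab")], D0)


# --- coverage gaps ---------------------------------------------------------


def test_gap_70_days_is_not_discontinuation():
    events = [ev(0, "ibrutinib", "oral", 30), ev(100, "ibrutinib", "oral", 30)]
    assert coverage_gap(events) == 70


def test_gap_95_days_reaches_discontinuation_threshold():
    events = [ev(0, "ibrutinib", "oral", 30), ev(125, "ibrutinib", "oral", 30)]
    assert coverage_gap(events) == 95


def test_single_event_gap_measured_to_censor_only():
    events = [ev(0, "rituximab")]
    assert coverage_gap(events) == 0
    assert coverage_gap(events, censor_date=D0 + timedelta(days=130)) == 100


# --- episode delimitation (hand-traced rules) ------------------------------


def test_infusion_only_discontinuation_ends_30_days_after_last_infusion():
    # B-R infusions through day 120, then nothing; enrollment to day 400
    events = []
    for day in (0, 60, 120):  # gaps stay under the 90-day threshold
        events += [ev(day, "bendamustine"), ev(day, "rituximab")]
    eps = build_episodes(events, D0 + timedelta(days=400))
    assert len(eps) == 1
    assert eps[0].end_reason == "discontinuation"
    assert days(eps[0].end) == 150  # 120 + 30


def test_oral_discontinuation_ends_90_days_after_supply_runs_out():
    events = [ev(0, "ibrutinib", "oral", 30), ev(30, "ibrutinib", "oral", 30)]
    eps = build_episodes(events, D0 + timedelta(days=400))
    assert len(eps) == 1
    assert eps[0].end_reason == "discontinuation"
    assert days(eps[0].end) == 59 + 90  # last covered day + 90


def test_oral_anchor_fill_date_variant():
    events = [ev(0, "ibrutinib", "oral", 30), ev(30, "ibrutinib", "oral", 30)]
    eps = build_episodes(events, D0 + timedelta(days=400),
                         EpisodeParams(oral_anchor="fill"))
    assert days(eps[0].end) == 30 + 90


def test_switch_ends_episode_one_day_before_new_agent():
    # ibrutinib fills covering through day 89, bortezomib claim day 60
    events = [ev(0, "ibrutinib", "oral", 30), ev(30, "ibrutinib", "oral", 30),
              ev(60, "ibrutinib", "oral", 30), ev(60, "bortezomib")]
    eps = build_episodes(events, D0 + timedelta(days=300))
    assert eps[0].end_reason == "switch"
    assert days(eps[0].end) == 59
    assert days(eps[1].start) == 60
    # the same-day ibrutinib fill joins the *new* episode's regimen
    assert eps[1].regimen == frozenset({"bortezomib", "ibrutinib"})


def test_rituximab_removal_does_not_end_episode_but_flags_it():
    events = []
    for c in range(6):  # R-CHOP, rituximab drops out after day 42
        if c * 21 <= 42:
            events.append(ev(c * 21, "rituximab"))
        events += [ev(c * 21, "cyclophosphamide"), ev(c * 21, "doxorubicin"),
                   ev(c * 21, "vincristine")]
    eps = build_episodes(events, D0 + timedelta(days=400))
    assert len(eps) == 1
    assert eps[0].rituximab_modified


def test_rituximab_addition_does_not_end_episode_but_flags_it():
    events = [ev(0, "bendamustine"), ev(28, "bendamustine"),
              ev(56, "bendamustine"), ev(56, "rituximab")]
    eps = build_episodes(events, D0 + timedelta(days=200))
    assert len(eps) == 1
    assert eps[0].regimen == frozenset({"bendamustine"})
    assert eps[0].rituximab_modified


def test_censoring_ends_episode_at_enrollment_end():
    events = [ev(0, "rituximab")]
    censor = D0 + timedelta(days=50)
    eps = build_episodes(events, censor)
    assert eps[0].end_reason == "censored" and eps[0].end == censor


# --- lines of therapy ------------------------------------------------------


def test_lines_numbered_by_start_date_and_labels_assigned():
    events = (
        [ev(c * 28, "bendamustine") for c in range(4)]
        + [ev(c * 28, "rituximab") for c in range(4)]
        + [ev(130, "ibrutinib", "oral", 30), ev(160, "ibrutinib", "oral", 30)]
    )
    eps = build_episodes(events, D0 + timedelta(days=700))
    assert [e.line for e in eps] == [1, 2]
    assert eps[0].label == "B-R"
    assert eps[1].label == "ibrutinib"


def test_later_line_rituximab_mono_is_maintenance_ambiguous():
    events = [ev(0, "ibrutinib", "oral", 30),
              ev(300, "rituximab"), ev(328, "rituximab")]
    eps = build_episodes(events, D0 + timedelta(days=700))
    assert eps[0].label == "ibrutinib"
    assert eps[1].label == "rituximab-maintenance-or-mono"
    assert not eps[1].ae_reportable
    # in first line it keeps its own label
    solo = build_episodes([ev(0, "rituximab")], D0 + timedelta(days=100))
    assert solo[0].label == "rituximab-mono" and solo[0].ae_reportable


# --- properties vs the brute-force oracle ----------------------------------

AGENTS = [
    ("alpha", "infusion"), ("beta", "infusion"), ("rituximab", "infusion"),
    ("oralx", "oral"), ("prednisone", "cortico"),
]

event_strategy = st.tuples(
    st.integers(min_value=0, max_value=320),      # day offset
    st.integers(min_value=0, max_value=len(AGENTS) - 1),
    st.integers(min_value=1, max_value=60),       # oral days supply
)


def _mk_events(raw):
    events = []
    for day, agent_i, supply in raw:
        name, kind = AGENTS[agent_i]
        if kind == "infusion":
            events.append(ev(day, name))
        elif kind == "oral":
            events.append(ev(day, name, "oral", supply))
        else:
            events.append(ev(day, name, "oral", supply, cortico=True))
    return events


def _compare_with_oracle(events, censor_days=420):
    censor = D0 + timedelta(days=censor_days)
    built = build_episodes(events, censor)
    got = [(e.start, e.end, e.regimen, e.end_reason, e.rituximab_modified)
           for e in built]
    want = brute_force_episodes(events, censor)
    assert got == want


@settings(max_examples=250, deadline=None, derandomize=True)
@given(st.lists(event_strategy, min_size=1, max_size=10))
def test_episode_builder_matches_day_by_day_simulation(raw):
    _compare_with_oracle(_mk_events(raw))


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(event_strategy, min_size=1, max_size=10))
def test_episodes_tile_the_treated_timeline(raw):
    events = _mk_events(raw)
    censor = D0 + timedelta(days=420)
    eps = build_episodes(events, censor)
    assert [e.line for e in eps] == list(range(1, len(eps) + 1))
    for a, b in zip(eps, eps[1:]):
        assert a.end < b.start  # ordered, non-overlapping
    for e in events:
        if e.is_corticosteroid:
            continue
        containing = [p for p in eps if p.start <= e.date <= p.end]
        starting = [p for p in eps if p.start == e.date]
        assert containing or starting
        assert len(containing) <= 1
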