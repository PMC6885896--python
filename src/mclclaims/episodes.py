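"""Treatment episodes, regimens and lines of therapy from treatment claims.

An episode starts at the first date of MCL-directed systemic treatment.  The
set of all antineoplastic agents observed in the first 35 days of the episode
defines the *regimen* (corticosteroids are recorded but never part of the
regimen identity).  The episode then runs until the first of:

* **switch** — a claim for an agent outside the regimen (other than
  rituximab) after the 35-day window; the episode ends one day before that
  claim.  Rituximab may be added or removed freely (flagged
  ``rituximab_modified``) without ending the episode.
* **discontinuation** — a gap of >= 90 days in treatment coverage.  Oral
  fills cover ``[fill, fill + days_supply - 1]``; an infusion covers its date
  plus a 30-day persistence window.  The episode then ends 90 days after the
  last covered oral day (regimens containing an oral agent anchor on the oral
  supply) or 30 days after the last infusion (infusion-only regimens).
* **censoring** — end of enrollment or of the study window.

Successive episodes are numbered as lines of therapy in start-date order.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

__all__ = [
    "TreatmentClaimEvent",
    "TreatmentEpisode",
    "EpisodeParams",
    "form_regimen",
    "coverage_gap",
    "detect_episode_end",
    "build_episodes",
    "assign_lines",
    "regimen_label",
    "RITUXIMAB",
]

RITUXIMAB = "rituximab"

#: canonical agent-set -> regimen label map (field-standard MCL regimens)
CANONICAL_REGIMENS: dict[frozenset[str], str] = {
    frozenset({"rituximab", "cyclophosphamide", "doxorubicin", "vincristine"}): "R-CHOP",
    frozenset({"bendamustine", "rituximab"}): "B-R",
    frozenset({"rituximab"}): "rituximab-mono",
    frozenset({"ibrutinib"}): "ibrutinib",
    frozenset({"acalabrutinib"}): "acalabrutinib",
    frozenset({"lenalidomide"}): "lenalidomide",
    frozenset({"bortezomib"}): "bortezomib",
    frozenset({"rituximab", "cyclophosphamide", "vincristine"}): "R-CVP",
    frozenset({"rituximab", "bendamustine", "cytarabine"}): "R-BAC",
    frozenset({"rituximab", "lenalidomide"}): "R-lenalidomide",
}

RITUX_LATER_LINE_LABEL = "rituximab-maintenance-or-mono"


@dataclass(frozen=True)
class TreatmentClaimEvent:
    """One dated treatment claim (infusion administration or oral fill)."""

    patient_id: str
    date: date
    agent: str
    route: str  # "oral" | "infusion"
    days_supply: int | None = None  # oral only
    claim_id: str | None = None
    is_corticosteroid: bool = False

    def __post_init__(self) -> None:
        if self.route == "oral":
            if self.days_supply is None or self.days_supply < 1:
                raise ValueError(f"oral event needs days_supply >= 1: {self}")
        elif self.route == "infusion":
            if self.days_supply is not None:
                raise ValueError(f"infusion event must not carry days_supply: {self}")
        else:
            raise ValueError(f"unknown route {self.route!r}")


@dataclass
class TreatmentEpisode:
    patient_id: str
    start: date
    end: date
    regimen: frozenset[str]
    end_reason: str  # "switch" | "discontinuation" | "censored"
    line: int = 0
    label: str = ""
    rituximab_modified: bool = False
    has_corticosteroid: bool = False
    ae_reportable: bool = True
    n_events: int = 0


@dataclass(frozen=True)
class EpisodeParams:
    """Tunable rule parameters (defaults follow the study conventions)."""

    window_days: int = 35
    gap_days: int = 90
    infusion_persist_days: int = 30
    # discontinuation end-date anchor for oral agents: "supply" ends the
    # episode 90 days after the last supply-covered day; "fill" 90 days after
    # the last fill date.
    oral_anchor: str = "supply"

    def __post_init__(self) -> None:
        if self.oral_anchor not in ("supply", "fill"):
            raise ValueError("oral_anchor must be 'supply' or 'fill'")
        if min(self.window_days, self.gap_days, self.infusion_persist_days) < 1:
            raise ValueError("episode rule parameters must be positive")


def _cov_end_excl(e: TreatmentClaimEvent, params: EpisodeParams) -> date:
    """First day NOT covered by this event."""
    if e.route == "oral":
        return e.date + timedelta(days=int(e.days_supply))
    return e.date + timedelta(days=params.infusion_persist_days)


def _sorted_check(events: list[TreatmentClaimEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.date < a.date:
            raise ValueError("treatment events must be sorted by date")


def form_regimen(
    events: list[TreatmentClaimEvent], episode_start: date, window_days: int = 35
) -> tuple[frozenset[str], bool]:
    """Agents observed within the regimen-formation window.

    Returns ``(agent set, corticosteroid seen)``.  The window is closed on
    day 0 through day ``window_days - 1`` inclusive.  Corticosteroids never
    enter the regimen identity; they are reported via the second element.
    """
    window_end = episode_start + timedelta(days=window_days - 1)
    if not any(
        e.date == episode_start and not e.is_corticosteroid for e in events
    ):
        raise ValueError(f"no treatment event at episode start {episode_start}")
    agents = {
        e.agent
        for e in events
        if episode_start <= e.date <= window_end and not e.is_corticosteroid
    }
    cortico = any(
        e.is_corticosteroid and episode_start <= e.date <= window_end for e in events
    )
    return frozenset(agents), cortico


def coverage_gap(
    events: list[TreatmentClaimEvent],
    params: EpisodeParams = EpisodeParams(),
    censor_date: date | None = None,
) -> int:
    """Maximal uncovered run (days) in a treatment event sequence.

    Coverage accumulates event by event; the gap before an event is measured
    from the running coverage end (exclusive) to the event date.  With a
    ``censor_date`` the tail gap from the last coverage end to censoring is
    included; a single event therefore has gap 0 without a censor date.
    """
    if not events:
        raise ValueError("coverage_gap needs at least one event")
    _sorted_check(events)
    cov_excl = _cov_end_excl(events[0], params)
    worst = 0
    for e in events[1:]:
        worst = max(worst, (e.date - cov_excl).days)
        cov_excl = max(cov_excl, _cov_end_excl(e, params))
    if censor_date is not None:
        worst = max(worst, (censor_date - cov_excl).days)
    return worst


def _discontinuation_end(
    ep_events: list[TreatmentClaimEvent], params: EpisodeParams
) -> date:
    oral = [e for e in ep_events if e.route == "oral"]
    if oral:
        if params.oral_anchor == "supply":
            anchor = max(e.date + timedelta(days=int(e.days_supply) - 1) for e in oral)
        else:
            anchor = max(e.date for e in oral)
        return anchor + timedelta(days=params.gap_days)
    last_infusion = max(e.date for e in ep_events)
    return last_infusion + timedelta(days=params.infusion_persist_days)


def detect_episode_end(
    treat_events: list[TreatmentClaimEvent],
    start_index: int,
    censor_date: date,
    params: EpisodeParams = EpisodeParams(),
) -> tuple[TreatmentEpisode, int]:
    """Delimit the episode beginning at ``treat_events[start_index]``.

    ``treat_events`` holds the patient's non-corticosteroid treatment events,
    date-sorted, all on or before ``censor_date``.  Returns the episode and
    the index of the first event of the next episode (``len(treat_events)``
    when none remains).
    """
    _sorted_check(treat_events)
    first = treat_events[start_index]
    start = first.date
    window_end = start + timedelta(days=params.window_days - 1)

    regimen: set[str] = set()
    ep_events: list[TreatmentClaimEvent] = []
    cov_excl: date | None = None
    end: date
    reason: str

    j = start_index
    while j < len(treat_events):
        e = treat_events[j]
        if e.date > censor_date:
            # defensive: events past censoring play no role
            break
        if e.date <= window_end:
            regimen.add(e.agent)
        else:
            gap = (e.date - cov_excl).days
            if gap >= params.gap_days:
                end, reason = _discontinuation_end(ep_events, params), "discontinuation"
                return _finalize(first, start, end, reason, regimen, ep_events,
                                 window_end), j
            if e.agent not in regimen and e.agent != RITUXIMAB:
                # the whole switch day belongs to the next episode: rewind any
                # same-day events already consumed
                end, reason = e.date - timedelta(days=1), "switch"
                k = j
                while k > start_index and treat_events[k - 1].date == e.date:
                    k -= 1
                ep_events = [x for x in ep_events if x.date < e.date]
                return _finalize(first, start, end, reason, regimen, ep_events,
                                 window_end), k
        ep_events.append(e)
        ce = _cov_end_excl(e, params)
        cov_excl = ce if cov_excl is None else max(cov_excl, ce)
        j += 1

    if (censor_date - cov_excl).days >= params.gap_days:
        end, reason = _discontinuation_end(ep_events, params), "discontinuation"
    else:
        end, reason = censor_date, "censored"
    return _finalize(first, start, end, reason, regimen, ep_events, window_end), j


def _finalize(first, start, end, reason, regimen, ep_events, window_end):
    # rituximab addition: a rituximab claim after the regimen window when
    # rituximab was not part of the starting regimen
    ritux_mod = RITUXIMAB not in regimen and any(
        e.agent == RITUXIMAB and e.date > window_end for e in ep_events
    )
    # rituximab removal: it was in the regimen but its coverage lapsed while
    # another regimen agent kept the episode going
    if RITUXIMAB in regimen:
        r_events = [e for e in ep_events if e.agent == RITUXIMAB]
        others = [e for e in ep_events if e.agent != RITUXIMAB]
        if r_events and others:
            persist = EpisodeParams().infusion_persist_days
            r_cov = max(
                e.date + timedelta(days=int(e.days_supply) if e.route == "oral" else persist)
                for e in r_events
            )
            if any(o.date >= r_cov for o in others):
                ritux_mod = True
    return TreatmentEpisode(
        patient_id=first.patient_id,
        start=start,
        end=max(end, start),
        regimen=frozenset(regimen),
        end_reason=reason,
        rituximab_modified=ritux_mod,
        n_events=len(ep_events),
    )


def build_episodes(
    events: list[TreatmentClaimEvent],
    censor_date: date,
    params: EpisodeParams = EpisodeParams(),
) -> list[TreatmentEpisode]:
    """Partition one patient's treatment events into ordered episodes.

    ``events`` may include corticosteroid events; these annotate episodes but
    never start, end or name them.  Events dated after ``censor_date`` are
    ignored.
    """
    events = sorted(
        [e for e in events if e.date <= censor_date],
        key=lambda e: (e.date, e.route, e.agent),
    )
    treat = [e for e in events if not e.is_corticosteroid]
    cortico = [e for e in events if e.is_corticosteroid]
    episodes: list[TreatmentEpisode] = []
    i = 0
    while i < len(treat):
        ep, i = detect_episode_end(treat, i, censor_date, params)
        window_end = ep.start + timedelta(days=params.window_days - 1)
        ep.has_corticosteroid = any(ep.start <= c.date <= window_end for c in cortico)
        episodes.append(ep)
    return assign_lines(episodes)


def regimen_label(regimen: frozenset[str]) -> str:
    """Canonical regimen name for an agent set; 'other:<agents>' if unmapped."""
    label = CANONICAL_REGIMENS.get(frozenset(regimen))
    if label is None:
        label = "other:" + "+".join(sorted(regimen))
    return label


def assign_lines(episodes: list[TreatmentEpisode]) -> list[TreatmentEpisode]:
    """Number episodes as lines of therapy and attach regimen labels.

    Rituximab monotherapy beyond the first line cannot be told apart from
    maintenance rituximab in claims, so such episodes are relabeled
    ``rituximab-maintenance-or-mono`` and excluded from per-regimen AE
    reporting (``ae_reportable=False``).
    """
    out = []
    for line, ep in enumerate(sorted(episodes, key=lambda ep: ep.start), start=1):
        label = regimen_label(ep.regimen)
        reportable = True
        if label == "rituximab-mono" and line >= 2:
            label = RITUX_LATER_LINE_LABEL
            reportable = False
        ep = replace_fields(ep, line=line, label=label, ae_reportable=reportable)
        out.append(ep)
    return out


def line_label(line: int) -> str:
    """Line-of-therapy display label; the analysis tracks three lines."""
    return str(line) if line <= 3 else "4+"


def replace_fields(ep: TreatmentEpisode, **kw) -> TreatmentEpisode:
    for k, v in kw.items():
        setattr(ep, k, v)
    return ep
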