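"""Independent brute-force oracle for the episode rules.

Simulates the treatment-episode rules literally, one calendar day at a time,
tracking an uncovered-day run counter instead of interval arithmetic.  Kept
deliberately separate from the library implementation so property tests can
compare the two paths.
"""

from __future__ import annotations

from datetime import date, timedelta


def _covers(e, day: date, persist: int) -> bool:
    if e.route == "oral":
        return e.date <= day <= e.date + timedelta(days=e.days_supply - 1)
    return e.date <= day <= e.date + timedelta(days=persist - 1)


def _disc_end(consumed, gap_days: int, persist: int) -> date:
    oral = [e for e in consumed if e.route == "oral"]
    if oral:
        last_covered = max(e.date + timedelta(days=e.days_supply - 1) for e in oral)
        return last_covered + timedelta(days=gap_days)
    return max(e.date for e in consumed) + timedelta(days=persist)


def brute_force_episodes(events, censor, window_days=35, gap_days=90, persist=30):
    """Day-by-day simulation; returns tuples
    (start, end, regimen frozenset, end_reason, rituximab_modified)."""
    evs = sorted(
        (e for e in events if not e.is_corticosteroid and e.date <= censor),
        key=lambda e: (e.date, e.route, e.agent),
    )
    out = []
    idx = 0
    while idx < len(evs):
        start = evs[idx].date
        wend = start + timedelta(days=window_days - 1)
        consumed, regimen = [], set()
        j = idx
        end = reason = None
        next_idx = len(evs)
        run = 0  # consecutive uncovered days before `day`
        day = start
        while day <= censor:
            todays = []
            while j < len(evs) and evs[j].date == day:
                todays.append(j)
                j += 1
            if day <= wend:
                for t in todays:
                    regimen.add(evs[t].agent)
                    consumed.append(evs[t])
            elif todays:
                if run >= gap_days:
                    reason = "discontinuation"
                    end = _disc_end(consumed, gap_days, persist)
                    next_idx = todays[0]
                    break
                if any(evs[t].agent not in regimen and evs[t].agent != "rituximab"
                       for t in todays):
                    reason = "switch"
                    end = day - timedelta(days=1)
                    next_idx = todays[0]  # the whole day starts the next episode
                    break
                for t in todays:
                    consumed.append(evs[t])
            covered_today = any(_covers(e, day, persist) for e in consumed)
            run = 0 if covered_today else run + 1
            day += timedelta(days=1)
        if reason is None:
            next_idx = j
            if run >= gap_days + 1:
                reason = "discontinuation"
                end = _disc_end(consumed, gap_days, persist)
            else:
                reason = "censored"
                end = censor
        ritux_mod = "rituximab" not in regimen and any(
            e.agent == "rituximab" and e.date > wend for e in consumed
        )
        if "rituximab" in regimen:
            r = [e for e in consumed if e.agent == "rituximab"]
            others = [e for e in consumed if e.agent != "rituximab"]
            if r and others:
                r_cov = max(
                    e.date + timedelta(days=e.days_supply if e.route == "oral" else persist)
                    for e in r
                )
                if any(o.date >= r_cov for o in others):
                    ritux_mod = True
        out.append((start, max(end, start), frozenset(regimen), reason, ritux_mod))
        idx = next_idx
    return out
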