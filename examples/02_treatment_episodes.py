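"""Build treatment episodes and lines of therapy from raw treatment events.

The rules: the agents seen in the first 35 days of an episode name the
regimen; a non-rituximab agent outside that window switches the episode
(ending it one day earlier); a >= 90-day gap in drug coverage discontinues it
(oral: 90 days after the supply ran out; infusion-only: 30 days after the
last administration); otherwise the episode is censored.
"""

from datetime import date, timedelta

from mclclaims.episodes import TreatmentClaimEvent, build_episodes, coverage_gap

D0 = date(2015, 1, 1)


def ev(day, agent, route="infusion", supply=None):
    return TreatmentClaimEvent("P1", D0 + timedelta(days=day), agent, route,
                               days_supply=supply)


# six R-CHOP cycles every 21 days, then a switch to ibrutinib on day 180
events = []
for cycle in range(6):
    for agent in ("rituximab", "cyclophosphamide", "doxorubicin", "vincristine"):
        events.append(ev(cycle * 21, agent))
for k in range(4):
    events.append(ev(180 + 30 * k, "ibrutinib", route="oral", supply=30))

episodes = build_episodes(events, censor_date=D0 + timedelta(days=720))
for ep in episodes:
    print(f"line {ep.line}: {ep.label:10s} {ep.start} -> {ep.end} "
          f"({ep.end_reason}; agents: {'+'.join(sorted(ep.regimen))})")

gap = coverage_gap([e for e in events if e.agent == "ibrutinib"])
print(f"\nlargest coverage gap within the ibrutinib fills: {gap} days")
# Line 1 ends the day before the first ibrutinib fill (a switch); line 2 ends
# 90 days after the last 30-day supply ran out (a discontinuation).
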