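"""Cohort selection: inclusion/exclusion cascade and attrition ledger.

The analytic cohort is built by a sequential filter cascade anchored on the
*index date* — the first MCL-treatment claim inside the index window.
Patients must carry an MCL diagnosis during the study period, be adults at
index, and be continuously enrolled for >= 12 months (365 days) before and
>= 30 days after index.  Patients already treated during the 12-month
baseline are excluded, except those indexed on ibrutinib (approved for
previously treated disease), who are retained for baseline description but
flagged ``excluded_from_outcomes``.  Each stage logs its surviving count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

from .codesets import CodeSets
from .episodes import TreatmentClaimEvent, TreatmentEpisode, RITUX_LATER_LINE_LABEL

__all__ = ["CohortParams", "find_index_date", "apply_attrition", "restrict_to_top_regimens"]

COHORT_COLUMNS = [
    "patient_id", "index_date", "index_agent", "age_at_index", "gender", "region",
    "plan_type", "censor_date", "followup_days", "prior_treated", "excluded_from_outcomes",
]


@dataclass(frozen=True)
class CohortParams:
    index_start: date = date(2013, 11, 1)
    index_end: date = date(2017, 12, 31)
    # the claims data window (study period); the data vendor's extract bounds
    study_start: date = date(2012, 11, 1)
    study_end: date = date(2018, 1, 31)
    baseline_days: int = 365
    min_followup_days: int = 30
    min_age: int = 18
    # spans separated by <= this many days count as continuous (claims
    # convention for administrative churn); 0 = strict
    enrollment_gap_tolerance: int = 0
    # optional baseline exclusions (procedure-code prefixes); None disables
    transplant_code_prefixes: tuple[str, ...] | None = None
    trial_code_prefixes: tuple[str, ...] | None = None


def _merge_spans(spans: list[tuple[date, date]], tolerance: int) -> list[tuple[date, date]]:
    spans = sorted(spans)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping enrollment spans: {(s1, e1)} / {(s2, e2)}")
    merged: list[tuple[date, date]] = []
    for s, e in spans:
        if merged and (s - merged[-1][1]).days - 1 <= tolerance:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _covering_span(merged: list[tuple[date, date]], d: date) -> tuple[date, date] | None:
    for s, e in merged:
        if s <= d <= e:
            return (s, e)
    return None


def find_index_date(
    events: list[TreatmentClaimEvent], params: CohortParams
) -> tuple[date, str] | None:
    """Earliest MCL-treatment event inside the index window -> (date, agent).

    Corticosteroid events never index a patient.  Returns None when the
    patient has no qualifying treatment claim in the window.
    """
    for e in sorted(events, key=lambda e: (e.date, e.route, e.agent)):
        if e.is_corticosteroid:
            continue
        if params.index_start <= e.date <= params.index_end:
            return e.date, e.agent
    return None


def apply_attrition(
    enrollment: pd.DataFrame,
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    events_by_patient: dict[str, list[TreatmentClaimEvent]],
    codesets: CodeSets,
    params: CohortParams = CohortParams(),
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the inclusion/exclusion cascade.

    Returns the cohort table (one row per retained patient) and the attrition
    ledger, a list of ``{"stage": ..., "n": ...}`` entries with monotonically
    non-increasing counts.
    """
    mcl_prefixes = tuple(codesets.mcl_dx_prefixes)
    ledger: list[dict] = []

    def log(stage: str, pids) -> set:
        pids = set(pids)
        ledger.append({"stage": stage, "n": len(pids)})
        return pids

    alive = log("enrolled members", enrollment["patient_id"].astype(str))

    # stage 1: >=1 MCL diagnosis claim during the study period
    med = medical.copy()
    med["patient_id"] = med["patient_id"].astype(str)
    has_mcl: set[str] = set()
    for row in med.itertuples(index=False):
        if not (params.study_start <= row.date <= params.study_end):
            continue
        dxs = str(row.dx_codes).replace(".", "").upper()
        for c in dxs.split(";"):
            if c and any(c.startswith(p) for p in mcl_prefixes):
                has_mcl.add(str(row.patient_id))
                break
    alive = log("MCL diagnosis in study period", alive & has_mcl)

    # stage 2: an index treatment inside the index window
    index_info: dict[str, tuple[date, str]] = {}
    for pid in alive:
        found = find_index_date(events_by_patient.get(pid, []), params)
        if found is not None:
            index_info[pid] = found
    alive = log("MCL treatment in index window", set(index_info))

    demo = enrollment.drop_duplicates("patient_id").set_index(
        enrollment.drop_duplicates("patient_id")["patient_id"].astype(str)
    )

    # stage 3: age >= 18 at index
    def age_at(pid: str) -> int:
        return index_info[pid][0].year - int(demo.loc[pid, "birth_year"])

    alive = log("adult at index", {p for p in alive if age_at(p) >= params.min_age})

    # stages 4-5: continuous enrollment around index
    spans_by_pid: dict[str, list[tuple[date, date]]] = {}
    for row in enrollment.itertuples(index=False):
        spans_by_pid.setdefault(str(row.patient_id), []).append((row.start, row.end))
    merged_by_pid = {
        pid: _merge_spans(sp, params.enrollment_gap_tolerance)
        for pid, sp in spans_by_pid.items()
    }

    def baseline_ok(pid: str) -> bool:
        idx = index_info[pid][0]
        span = _covering_span(merged_by_pid.get(pid, []), idx)
        return span is not None and span[0] <= idx - timedelta(days=params.baseline_days)

    alive = log("12-month pre-index enrollment", {p for p in alive if baseline_ok(p)})

    def followup_ok(pid: str) -> bool:
        idx = index_info[pid][0]
        span = _covering_span(merged_by_pid[pid], idx)
        return span is not None and span[1] >= idx + timedelta(days=params.min_followup_days - 1)

    alive = log("30-day post-index enrollment", {p for p in alive if followup_ok(p)})

    # stage 6: newly treated (no baseline MCL treatment), ibrutinib exception
    prior_treated: dict[str, bool] = {}
    for pid in alive:
        idx = index_info[pid][0]
        lo = idx - timedelta(days=params.baseline_days)
        prior_treated[pid] = any(
            not e.is_corticosteroid and lo <= e.date < idx
            for e in events_by_patient.get(pid, [])
        )
    keep = set()
    for pid in alive:
        if not prior_treated[pid] or index_info[pid][1] == "ibrutinib":
            keep.add(pid)
    alive = log("newly treated (ibrutinib exception)", keep)

    # stage 7: optional baseline transplant / trial-participation exclusions
    for name, prefixes in (
        ("no baseline stem-cell transplant", params.transplant_code_prefixes),
        ("no clinical-trial participation", params.trial_code_prefixes),
    ):
        if prefixes is None:
            continue
        flagged = set()
        for row in med.itertuples(index=False):
            pid = str(row.patient_id)
            if pid not in alive or pid not in index_info:
                continue
            idx = index_info[pid][0]
            code = str(row.code).replace(".", "").upper()
            if code and any(code.startswith(p) for p in prefixes) and row.date < idx:
                flagged.add(pid)
        alive = log(name, alive - flagged)

    rows = []
    for pid in sorted(alive):
        idx, agent = index_info[pid]
        span = _covering_span(merged_by_pid[pid], idx)
        censor = min(span[1], params.study_end)
        rows.append({
            "patient_id": pid,
            "index_date": idx,
            "index_agent": agent,
            "age_at_index": age_at(pid),
            "gender": demo.loc[pid, "gender"],
            "region": demo.loc[pid, "region"],
            "plan_type": demo.loc[pid, "plan_type"],
            "censor_date": censor,
            "followup_days": (censor - idx).days + 1,
            "prior_treated": prior_treated[pid],
            "excluded_from_outcomes": prior_treated[pid] and agent == "ibrutinib",
        })
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return cohort, ledger


def restrict_to_top_regimens(
    cohort: pd.DataFrame,
    episodes_by_patient: dict[str, list[TreatmentEpisode]],
    k: int = 4,
) -> tuple[pd.DataFrame, list[str], list[dict]]:
    """Keep patients with >=1 episode among the k most common regimens.

    Regimens are ranked by the number of distinct patients receiving them in
    any line; later-line rituximab monotherapy counts toward rituximab
    monotherapy for ranking (the claims stream cannot separate maintenance
    from monotherapy).  Rank ties break alphabetically for determinism.
    Returns (analytic cohort, top regimen labels, ledger entries).
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def rank_label(ep: TreatmentEpisode) -> str:
        return "rituximab-mono" if ep.label == RITUX_LATER_LINE_LABEL else ep.label

    patients_by_regimen: dict[str, set[str]] = {}
    cohort_pids = set(cohort["patient_id"].astype(str))
    for pid, eps in episodes_by_patient.items():
        if pid not in cohort_pids:
            continue
        for ep in eps:
            patients_by_regimen.setdefault(rank_label(ep), set()).add(pid)
    ranked = sorted(patients_by_regimen.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    top = [name for name, _ in ranked[:k]]
    keep = set().union(*(patients_by_regimen[name] for name in top)) if top else set()
    analytic = cohort[cohort["patient_id"].astype(str).isin(keep)].reset_index(drop=True)
    ledger = [{"stage": f"received a top-{k} regimen", "n": len(analytic)}]
    return analytic, top, ledger
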