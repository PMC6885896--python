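"""Incident adverse-event detection and AE-burden tabulation.

An AE category is *incident* for a patient when >= 1 claim carrying that
category's diagnosis codes falls inside a treatment episode and no claim for
the same category exists before that episode's treatment initiation date.
The look-back for prior evidence defaults to all observable history (a
baseline-window variant is available).  Secondary malignancy is stricter: it
requires >= 2 claims for the same cancer (same 3-character code family by
default) >= 7 days apart within an episode, and the unspecified
lymphoid/hematopoietic families are excluded at the code-set level.

Patients flagged ``excluded_from_outcomes`` (ibrutinib-indexed with prior
treatment) contribute no incident AEs.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .codesets import CodeSets, matches_category, normalize_code
from .episodes import TreatmentEpisode

__all__ = [
    "IncidentAE",
    "detect_incident_aes",
    "assign_burden_strata",
    "ae_table_by_regimen",
    "stratum_for_count",
    "STRATA",
]

STRATA = ("0", "1-2", "3-5", "6+")


@dataclass(frozen=True)
class IncidentAE:
    patient_id: str
    ae: str
    date: date
    line: int
    regimen_label: str


def stratum_for_count(n: int) -> str:
    if n <= 0:
        return "0"
    if n <= 2:
        return "1-2"
    if n <= 5:
        return "3-5"
    return "6+"


def _ae_claims_by_patient(
    medical: pd.DataFrame, codesets: CodeSets
) -> dict[str, dict[str, list[tuple[date, str]]]]:
    """patient -> category -> [(claim date, normalized code), ...] sorted."""
    cats = codesets.ae_codes.categories
    out: dict[str, dict[str, list[tuple[date, str]]]] = {}
    for row in medical.itertuples(index=False):
        dxs = str(row.dx_codes)
        if not dxs:
            continue
        pid = str(row.patient_id)
        for raw in dxs.split(";"):
            if not raw:
                continue
            code = normalize_code(raw)
            for name, cat in cats.items():
                if matches_category(code, cat):
                    out.setdefault(pid, {}).setdefault(name, []).append((row.date, code))
    for pid in out:
        for name in out[pid]:
            out[pid][name].sort()
    return out


def _qualifying_malignancy(
    in_ep: list[tuple[date, str]],
    prior: list[tuple[date, str]],
    same_cancer: str,
    min_gap_days: int = 7,
) -> date | None:
    """First date of a qualifying, previously unseen cancer; None otherwise."""

    def key(code: str) -> str:
        return code[:3] if same_cancer == "family" else code

    prior_keys = {key(c) for _, c in prior}
    by_key: dict[str, list[date]] = {}
    for d, c in in_ep:
        by_key.setdefault(key(c), []).append(d)
    best: date | None = None
    for k, dates in by_key.items():
        if k in prior_keys or len(dates) < 2:
            continue
        if (max(dates) - min(dates)).days >= min_gap_days:
            first = min(dates)
            best = first if best is None else min(best, first)
    return best


def detect_incident_aes(
    medical: pd.DataFrame,
    episodes_by_patient: dict[str, list[TreatmentEpisode]],
    codesets: CodeSets,
    excluded_patients: set[str] | None = None,
    lookback: str = "all",
    baseline_days: int = 365,
    same_cancer: str = "family",
) -> list[IncidentAE]:
    """Detect incident AEs against computed episode boundaries.

    ``lookback`` — "all" (default): any earlier claim for the category blocks
    incidence; "baseline": only claims within ``baseline_days`` before the
    episode start block.  ``same_cancer`` — granularity of the secondary-
    malignancy two-claim rule ("family" = 3-character code family, or
    "exact").
    """
    if lookback not in ("all", "baseline"):
        raise ValueError("lookback must be 'all' or 'baseline'")
    excluded_patients = excluded_patients or set()
    claims = _ae_claims_by_patient(medical, codesets)
    rules = {
        name: cat.rule for name, cat in codesets.ae_codes.categories.items()
    }
    out: list[IncidentAE] = []
    for pid, eps in episodes_by_patient.items():
        if pid in excluded_patients:
            continue
        by_cat = claims.get(pid, {})
        for name, cat_claims in by_cat.items():
            hit: IncidentAE | None = None
            for ep in sorted(eps, key=lambda e: e.start):
                lo = (
                    ep.start - timedelta(days=baseline_days)
                    if lookback == "baseline"
                    else date.min
                )
                prior = [(d, c) for d, c in cat_claims if lo <= d < ep.start]
                in_ep = [(d, c) for d, c in cat_claims if ep.start <= d <= ep.end]
                if rules.get(name) == "two_claims_7d":
                    qd = _qualifying_malignancy(in_ep, prior, same_cancer)
                    if qd is not None:
                        hit = IncidentAE(pid, name, qd, ep.line, ep.label)
                        break
                else:
                    if prior:
                        if lookback == "all":
                            # earlier evidence also precedes every later episode
                            break
                        continue
                    if in_ep:
                        hit = IncidentAE(pid, name, in_ep[0][0], ep.line, ep.label)
                        break
            if hit is not None:
                out.append(hit)
    out.sort(key=lambda a: (a.patient_id, a.ae))
    return out


def assign_burden_strata(
    incident_aes: list[IncidentAE], patient_ids: list[str]
) -> pd.DataFrame:
    """Per-patient unique-AE count and burden stratum (0 / 1-2 / 3-5 / >=6).

    ``patient_ids`` is the analyzed cohort; patients with no incident AEs are
    retained in the zero stratum so the strata partition the cohort.
    """
    counts: dict[str, set[str]] = {pid: set() for pid in patient_ids}
    for ae in incident_aes:
        if ae.patient_id in counts:
            counts[ae.patient_id].add(ae.ae)
    rows = [
        {"patient_id": pid, "ae_count": len(s), "stratum": stratum_for_count(len(s))}
        for pid, s in counts.items()
    ]
    return pd.DataFrame(rows, columns=["patient_id", "ae_count", "stratum"]).sort_values(
        "patient_id", ignore_index=True
    )


def ae_table_by_regimen(
    incident_aes: list[IncidentAE],
    episodes_by_patient: dict[str, list[TreatmentEpisode]],
    ae_names: list[str] | None = None,
) -> pd.DataFrame:
    """Incident-AE frequencies by regimen (tidy analogue of a toxicity table).

    Denominator for a regimen = patients with >= 1 AE-reportable episode of
    that regimen (later-line rituximab monotherapy is never reportable).
    Rows: patient count, no-AE / >=1-AE splits, per-patient AE count summary,
    and each AE category's n and %.  Every percentage carries its numerator
    and denominator.
    """
    patients_by_reg: dict[str, set[str]] = {}
    for pid, eps in episodes_by_patient.items():
        for ep in eps:
            if ep.ae_reportable:
                patients_by_reg.setdefault(ep.label, set()).add(pid)

    ae_by_reg_patient: dict[str, dict[str, set[str]]] = {}
    for ae in incident_aes:
        ae_by_reg_patient.setdefault(ae.regimen_label, {}).setdefault(
            ae.patient_id, set()
        ).add(ae.ae)

    if ae_names is None:
        ae_names = sorted({ae.ae for ae in incident_aes})

    rows = []
    for reg in sorted(patients_by_reg):
        denom_pids = patients_by_reg[reg]
        denom = len(denom_pids)
        per_patient = ae_by_reg_patient.get(reg, {})
        counts = np.array([len(per_patient.get(pid, ())) for pid in sorted(denom_pids)])
        n_ge1 = int((counts >= 1).sum())

        def add(measure, n, value=None):
            rows.append({
                "regimen": reg, "measure": measure, "n": n, "denominator": denom,
                "pct": (100.0 * n / denom) if (n is not None and denom) else np.nan,
                "value": value,
            })

        add("patients", denom)
        add("no_ae", denom - n_ge1)
        add("ge1_ae", n_ge1)
        rows.append({
            "regimen": reg, "measure": "ae_count_mean", "n": None, "denominator": denom,
            "pct": np.nan, "value": float(counts.mean()) if denom else np.nan,
        })
        rows.append({
            "regimen": reg, "measure": "ae_count_median", "n": None, "denominator": denom,
            "pct": np.nan, "value": float(np.median(counts)) if denom else np.nan,
        })
        for q, nm in ((25, "ae_count_q1"), (75, "ae_count_q3")):
            rows.append({
                "regimen": reg, "measure": nm, "n": None, "denominator": denom,
                "pct": np.nan,
                "value": float(np.percentile(counts, q)) if denom else np.nan,
            })
        for name in ae_names:
            n_cat = sum(1 for pid in denom_pids if name in per_patient.get(pid, ()))
            add(f"ae:{name}", n_cat)
    return pd.DataFrame(rows, columns=["regimen", "measure", "n", "denominator", "pct", "value"])
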