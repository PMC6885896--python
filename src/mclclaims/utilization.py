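"""Per-patient-per-month (PPPM) healthcare resource use and cost summaries.

Follow-up claims are bucketed into five categories — hospitalization
(inpatient admissions), ED visits, office visits, pharmacy, and other
outpatient services — each measured under two scopes: all-cause and
MCL-related (claims carrying an MCL diagnosis at any position, or claims for
MCL-directed treatments).  Counts and costs divide by follow-up months
(days / 30.4375).  Allowed amounts are inflated to reference-year (2017)
dollars and carried as integer cents so that category costs sum to the total
exactly.

Facility claims with overlapping inpatient service spans form one admission;
length of stay is discharge minus admit date (minimum 1 day).  An admission
counts as MCL-related if any claim in its bundle is; admission *costs* are
subset at the claim level.

Outpatient medical claims carrying a drug-administration code for an
MCL-directed treatment are counted under the pharmacy category together with
dispensed prescriptions (drug acquisition/administration), not as office
visits; inpatient claims stay under hospitalization regardless of codes.
"""

from __future__ import annotations

from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .codesets import CodeSets, CPITable, normalize_code

__all__ = [
    "inflate_cents",
    "inflate_cost",
    "attribute_mcl_related",
    "summarize_pppm",
    "pppm_stratum_table",
    "MONTH_DAYS",
    "CATEGORIES",
]

MONTH_DAYS = 30.4375  # 365.25 / 12
CATEGORIES = ("hospitalization", "ed", "office", "pharmacy", "other")


def inflate_cents(cents: int, year: int, cpi: CPITable) -> int:
    """Inflate an integer-cent amount to reference-year cents.

    Rounds half away from zero; negative (reversal) amounts keep their sign.
    """
    f = cpi.factor(year)
    scaled = abs(int(cents)) * f
    out = int(np.floor(scaled + 0.5))
    return out if cents >= 0 else -out


def inflate_cost(amount: float, year: int, cpi: CPITable) -> float:
    """Inflate a dollar amount to reference-year dollars."""
    return float(amount) * cpi.factor(year)


def attribute_mcl_related(claim: Mapping, codesets: CodeSets) -> bool:
    """True iff any diagnosis matches the MCL prefixes or the claim's
    drug/procedure code is an MCL-directed treatment."""
    dx = claim.get("dx_codes", "") or ""
    if isinstance(dx, str):
        dx = [c for c in dx.split(";") if c]
    for c in dx:
        cn = normalize_code(c)
        if any(cn.startswith(p) for p in codesets.mcl_dx_prefixes):
            return True
    code = claim.get("code", "") or ""
    if code:
        entry = codesets.drug_catalog.lookup(code)
        if entry is not None and entry.is_mcl_treatment:
            return True
    return False


def _medical_category(claim: Mapping, codesets: CodeSets) -> str:
    if claim["setting"] == "inpatient":
        return "hospitalization"
    code = claim.get("code", "") or ""
    if code:
        entry = codesets.drug_catalog.lookup(code)
        if entry is not None and entry.is_mcl_treatment:
            return "pharmacy"
    if claim["setting"] in ("ed", "office"):
        return claim["setting"]
    return "other"


def _bundle_admissions(rows: list[dict]) -> list[list[dict]]:
    """Group inpatient claims with overlapping service spans."""
    rows = sorted(rows, key=lambda r: (r["date"], r["end_date"]))
    bundles: list[list[dict]] = []
    cur_end: date | None = None
    for r in rows:
        if bundles and cur_end is not None and r["date"] <= cur_end:
            bundles[-1].append(r)
            cur_end = max(cur_end, r["end_date"])
        else:
            bundles.append([r])
            cur_end = r["end_date"]
    return bundles


def summarize_pppm(
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    cohort: pd.DataFrame,
    codesets: CodeSets,
    month_days: float = MONTH_DAYS,
) -> pd.DataFrame:
    """One row per analyzed patient with PPPM utilization and costs.

    ``cohort`` must carry ``index_date``, ``censor_date`` and
    ``excluded_from_outcomes``; flagged patients are dropped (they are
    described at baseline only).  Patients with zero-length follow-up are
    excluded.  Cost columns come in inflated integer cents
    (``{scope}_{cat}_cents`` and ``{scope}_total_cents``) alongside PPPM
    dollars.
    """
    analyzed = cohort[~cohort["excluded_from_outcomes"].astype(bool)]
    idx_by_pid = {
        str(r.patient_id): (r.index_date, r.censor_date)
        for r in analyzed.itertuples(index=False)
    }

    med_rows: dict[str, list[dict]] = {pid: [] for pid in idx_by_pid}
    for row in medical.itertuples(index=False):
        pid = str(row.patient_id)
        win = idx_by_pid.get(pid)
        if win is None or not (win[0] <= row.date <= win[1]):
            continue
        claim = {
            "date": row.date, "end_date": row.end_date, "setting": row.setting,
            "code": row.code, "dx_codes": row.dx_codes,
            "cents": inflate_cents(int(row.allowed_cents), row.date.year, codesets.cpi),
        }
        claim["mcl"] = attribute_mcl_related(claim, codesets)
        claim["category"] = _medical_category(claim, codesets)
        med_rows[pid].append(claim)

    rx_rows: dict[str, list[dict]] = {pid: [] for pid in idx_by_pid}
    for row in pharmacy.itertuples(index=False):
        pid = str(row.patient_id)
        win = idx_by_pid.get(pid)
        if win is None or not (win[0] <= row.date <= win[1]):
            continue
        claim = {
            "date": row.date, "code": row.code, "dx_codes": "",
            "cents": inflate_cents(int(row.allowed_cents), row.date.year, codesets.cpi),
        }
        claim["mcl"] = attribute_mcl_related(claim, codesets)
        rx_rows[pid].append(claim)

    out = []
    for pid, (idx, censor) in idx_by_pid.items():
        followup_days = (censor - idx).days + 1
        if followup_days <= 0:
            continue
        months = followup_days / month_days
        rec: dict = {"patient_id": pid, "followup_months": months}

        med = med_rows[pid]
        inpat = [c for c in med if c["category"] == "hospitalization"]
        bundles = _bundle_admissions(inpat)
        for scope in ("all", "mcl"):
            sel = (lambda c: True) if scope == "all" else (lambda c: c["mcl"])
            b_sel = [b for b in bundles if any(sel(c) for c in b)]
            n_adm = len(b_sel)
            los = [
                max((max(c["end_date"] for c in b) - min(c["date"] for c in b)).days, 1)
                for b in b_sel
            ]
            counts = {
                "hospitalization": n_adm,
                "ed": sum(1 for c in med if c["category"] == "ed" and sel(c)),
                "office": sum(1 for c in med if c["category"] == "office" and sel(c)),
                "other": sum(1 for c in med if c["category"] == "other" and sel(c)),
                "pharmacy": sum(1 for c in rx_rows[pid] if sel(c))
                + sum(1 for c in med if c["category"] == "pharmacy" and sel(c)),
            }
            cents = {
                "hospitalization": sum(c["cents"] for c in inpat if sel(c)),
                "ed": sum(c["cents"] for c in med if c["category"] == "ed" and sel(c)),
                "office": sum(c["cents"] for c in med if c["category"] == "office" and sel(c)),
                "other": sum(c["cents"] for c in med if c["category"] == "other" and sel(c)),
                "pharmacy": sum(c["cents"] for c in rx_rows[pid] if sel(c))
                + sum(c["cents"] for c in med if c["category"] == "pharmacy" and sel(c)),
            }
            total = sum(cents.values())
            rec[f"{scope}_total_cents"] = total
            rec[f"{scope}_total_cost_pppm"] = total / 100.0 / months
            for cat in CATEGORIES:
                rec[f"{scope}_{cat}_pppm"] = counts[cat] / months
                rec[f"{scope}_{cat}_cents"] = cents[cat]
                rec[f"{scope}_{cat}_cost_pppm"] = cents[cat] / 100.0 / months
                rec[f"{scope}_any_{cat}"] = counts[cat] > 0
            rec[f"{scope}_los_per_admission"] = (sum(los) / n_adm) if n_adm else 0.0
        out.append(rec)
    if not out:
        return pd.DataFrame(columns=["patient_id", "followup_months"])
    return pd.DataFrame(out).sort_values("patient_id", ignore_index=True)


def pppm_stratum_table(pppm: pd.DataFrame, burden: pd.DataFrame) -> pd.DataFrame:
    """Stratum-level summary of PPPM measures by AE burden (tidy).

    Strata: ``all`` plus the burden groups 0 / 1-2 / 3-5 / >=6.  For any-use
    flags reports n and %, for continuous measures mean/SD/median; every row
    carries its denominator.
    """
    df = pppm.merge(burden[["patient_id", "stratum"]], on="patient_id", how="left")
    groups = [("all", df)] + [(s, g) for s, g in df.groupby("stratum")]
    rows = []
    for stratum, g in groups:
        n = len(g)
        for col in sorted(c for c in df.columns if c not in ("patient_id", "stratum")):
            if g[col].dtype == bool:
                k = int(g[col].sum())
                rows.append({
                    "stratum": stratum, "measure": col, "n": k, "denominator": n,
                    "pct": 100.0 * k / n if n else np.nan,
                    "mean": np.nan, "sd": np.nan, "median": np.nan,
                })
            elif np.issubdtype(g[col].dtype, np.number):
                rows.append({
                    "stratum": stratum, "measure": col, "n": None, "denominator": n,
                    "pct": np.nan,
                    "mean": float(g[col].mean()) if n else np.nan,
                    "sd": float(g[col].std(ddof=1)) if n > 1 else np.nan,
                    "median": float(g[col].median()) if n else np.nan,
                })
    return pd.DataFrame(rows)
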