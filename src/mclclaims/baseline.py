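"""Baseline demographic and clinical measures over the 12-month pre-index window.

All measures use only claims strictly before the index date.  Clinical
content — the Charlson Comorbidity Index (CCI) mapping, comorbidity
definitions and the atrial-fibrillation risk-factor score — is fully
config-driven (see :mod:`mclclaims.codesets`); the shipped defaults are
illustrative.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Iterable

import numpy as np
import pandas as pd

from .codesets import CodeSets, CCICondition, AFRiskModel, normalize_code
from .utilization import inflate_cents

__all__ = [
    "compute_cci",
    "compute_pill_burden",
    "classify_af_risk",
    "baseline_profiles",
]


def compute_cci(dx_codes: Iterable[str], cci_map: dict[str, CCICondition]) -> int:
    """Weighted count of distinct Charlson conditions present in the codes."""
    codes = [normalize_code(c) for c in dx_codes]
    total = 0
    for cond in cci_map.values():
        if any(c.startswith(p) for c in codes for p in cond.prefixes):
            total += cond.weight
    return total


def compute_pill_burden(
    fills: pd.DataFrame, index_date: date, window_days: int = 30
) -> float:
    """Mean pills/day over the ``window_days`` pre-index: sum(quantity)/window.

    ``fills`` are the patient's pharmacy claims (columns ``date``,
    ``quantity``).  Fills dated exactly ``index - window_days`` are included;
    the index date itself is not.  Raises on negative quantities.
    """
    if (fills["quantity"] < 0).any():
        raise ValueError("negative dispensed quantity in pharmacy claims")
    lo = index_date - timedelta(days=window_days)
    mask = fills["date"].map(lambda d: lo <= d < index_date)
    return float(fills.loc[mask, "quantity"].sum()) / window_days


def classify_af_risk(dx_codes: Iterable[str], model: AFRiskModel) -> str:
    """Point score over baseline risk-factor code lists; >= threshold -> high."""
    if model is None:
        raise ValueError("af_risk model configuration is required")
    codes = [normalize_code(c) for c in dx_codes]
    points = 0
    for f in model.factors.values():
        if any(c.startswith(p) for c in codes for p in f["prefixes"]):
            points += int(f["points"])
    return "high" if points >= model.threshold else "low"


def baseline_profiles(
    cohort: pd.DataFrame,
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    codesets: CodeSets,
    baseline_days: int = 365,
    baseline_months: float = 12.0,
) -> pd.DataFrame:
    """Per-patient baseline profile (demographics, CCI, comorbidity flags,
    AF risk, daily pill burden, baseline all-cause cost PPPM in 2017 USD).

    Pill burden is reported only for patients with >= 1 oral MCL-treatment
    fill anywhere in their record (NaN otherwise), mirroring how an oral
    pill-count measure is only meaningful for oral-drug users.  Baseline cost
    divides by a fixed 12 months: the cohort guarantees full baseline
    coverage.
    """
    pids = cohort["patient_id"].astype(str)
    idx_by_pid = dict(zip(pids, cohort["index_date"]))

    med = medical[medical["patient_id"].astype(str).isin(set(pids))].copy()
    med["patient_id"] = med["patient_id"].astype(str)
    rx = pharmacy[pharmacy["patient_id"].astype(str).isin(set(pids))].copy()
    rx["patient_id"] = rx["patient_id"].astype(str)

    oral_mcl_codes = {
        e.code for e in codesets.drug_catalog.entries
        if e.route == "oral" and e.is_mcl_treatment
    }
    oral_eligible = set(
        rx.loc[rx["code"].map(lambda c: normalize_code(c) in oral_mcl_codes), "patient_id"]
    )

    # baseline dx codes per patient
    dx_by_pid: dict[str, list[str]] = {pid: [] for pid in pids}
    for row in med.itertuples(index=False):
        idx = idx_by_pid[row.patient_id]
        if idx - timedelta(days=baseline_days) <= row.date < idx and row.dx_codes:
            dx_by_pid[row.patient_id].extend(
                normalize_code(c) for c in str(row.dx_codes).split(";") if c
            )

    # baseline allowed amounts, inflated to reference-year cents
    def _baseline_cents(df: pd.DataFrame) -> dict[str, int]:
        out: dict[str, int] = {}
        for row in df.itertuples(index=False):
            idx = idx_by_pid[row.patient_id]
            if idx - timedelta(days=baseline_days) <= row.date < idx:
                cents = inflate_cents(int(row.allowed_cents), row.date.year, codesets.cpi)
                out[row.patient_id] = out.get(row.patient_id, 0) + cents
        return out

    med_cents = _baseline_cents(med)
    rx_cents = _baseline_cents(rx)

    rx_by_pid = {pid: grp for pid, grp in rx.groupby("patient_id")}
    comorb = codesets.comorbidity_codes

    rows = []
    for rec in cohort.itertuples(index=False):
        pid = str(rec.patient_id)
        dx = dx_by_pid[pid]
        flags = {
            f"comorb_{name}": any(c.startswith(p) for c in dx for p in prefixes)
            for name, prefixes in comorb.items()
        }
        if pid in oral_eligible:
            fills = rx_by_pid.get(pid)
            burden = (
                compute_pill_burden(fills, rec.index_date) if fills is not None else 0.0
            )
        else:
            burden = np.nan
        rows.append({
            "patient_id": pid,
            "age_at_index": rec.age_at_index,
            "gender": rec.gender,
            "region": rec.region,
            "plan_type": rec.plan_type,
            "cci": compute_cci(dx, codesets.cci),
            "af_risk": classify_af_risk(dx, codesets.af_risk),
            "pill_burden": burden,
            "baseline_cost_pppm": (med_cents.get(pid, 0) + rx_cents.get(pid, 0))
            / 100.0 / baseline_months,
            **flags,
        })
    return pd.DataFrame(rows).sort_values("patient_id", ignore_index=True)
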