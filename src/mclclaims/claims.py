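"""Claim-table schemas and converters.

The pipeline consumes three tabular inputs, carried as pandas DataFrames and
serialized as plain CSV:

* **enrollment** — one row per continuous-coverage span, with member
  demographics: ``patient_id, start, end, birth_year, gender, region,
  plan_type``.
* **medical** — ``claim_id, patient_id, date, end_date, setting, code,
  dx_codes, allowed_cents, admission_id``.  ``setting`` is one of
  ``inpatient | ed | office | other``; ``dx_codes`` is a ';'-joined list
  (may be empty); ``code`` is the HCPCS/procedure code ('' if none);
  ``admission_id`` groups facility claims of one inpatient stay ('' if none).
* **pharmacy** — ``claim_id, patient_id, date, code, days_supply, quantity,
  allowed_cents`` with ``code`` the NDC.

Money travels as integer cents to keep cost partitions exact.
"""

from __future__ import annotations

from datetime import date, datetime
from pathlib import Path

import pandas as pd

from .codesets import CodeSets
from .episodes import TreatmentClaimEvent

ENROLLMENT_COLUMNS = ["patient_id", "start", "end", "birth_year", "gender", "region", "plan_type"]
MEDICAL_COLUMNS = [
    "claim_id", "patient_id", "date", "end_date", "setting", "code",
    "dx_codes", "allowed_cents", "admission_id",
]
PHARMACY_COLUMNS = ["claim_id", "patient_id", "date", "code", "days_supply", "quantity", "allowed_cents"]

_DATE_COLS = {"enrollment": ["start", "end"], "medical": ["date", "end_date"], "pharmacy": ["date"]}


def to_date(v) -> date:
    """Coerce ISO strings / timestamps to ``datetime.date``."""
    if isinstance(v, date) and not isinstance(v, datetime):
        return v
    if isinstance(v, datetime):
        return v.date()
    return datetime.strptime(str(v)[:10], "%Y-%m-%d").date()


def _coerce_dates(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        df[c] = df[c].map(to_date)
    return df


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    """Write the claim tables as CSV (ISO dates, deterministic row order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)


def read_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Read enrollment/medical/pharmacy CSVs written by :func:`write_tables`."""
    indir = Path(indir)
    out: dict[str, pd.DataFrame] = {}
    for name in ("enrollment", "medical", "pharmacy"):
        df = pd.read_csv(
            indir / f"{name}.csv",
            dtype={"patient_id": str, "code": str, "dx_codes": str, "claim_id": str,
                   "admission_id": str},
            keep_default_na=False,
        )
        out[name] = _coerce_dates(df, _DATE_COLS[name])
    return out


def treatment_events(
    medical: pd.DataFrame, pharmacy: pd.DataFrame, codesets: CodeSets
) -> dict[str, list[TreatmentClaimEvent]]:
    """Extract per-patient treatment events from the claim tables.

    Catalog routes are enforced at lookup: oral agents are recognized only on
    pharmacy claims, infused agents only on medical claims; a claim whose code
    sits on the wrong table is not a treatment event.  Corticosteroid events
    are included (they annotate episodes without defining them).
    """
    catalog = codesets.drug_catalog
    out: dict[str, list[TreatmentClaimEvent]] = {}

    for row in medical.itertuples(index=False):
        code = getattr(row, "code", "") or ""
        entry = catalog.lookup(code) if code else None
        if entry is None or entry.route != "infusion":
            continue
        out.setdefault(str(row.patient_id), []).append(
            TreatmentClaimEvent(
                patient_id=str(row.patient_id),
                date=to_date(row.date),
                agent=entry.agent,
                route="infusion",
                claim_id=str(row.claim_id),
                is_corticosteroid=entry.is_corticosteroid,
            )
        )
    for row in pharmacy.itertuples(index=False):
        entry = catalog.lookup(str(row.code))
        if entry is None or entry.route != "oral":
            continue
        out.setdefault(str(row.patient_id), []).append(
            TreatmentClaimEvent(
                patient_id=str(row.patient_id),
                date=to_date(row.date),
                agent=entry.agent,
                route="oral",
                days_supply=int(row.days_supply),
                claim_id=str(row.claim_id),
                is_corticosteroid=entry.is_corticosteroid,
            )
        )
    for pid in out:
        out[pid].sort(key=lambda e: (e.date, e.route, e.agent))
    return out
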