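"""Code lists and the drug catalog consulted by every pipeline stage.

Administrative claims identify everything by code: diagnoses by ICD-9-CM /
ICD-10-CM codes, drugs by NDC, and administered (infused) drugs by HCPCS
procedure codes.  This module loads a single JSON configuration holding

* the drug catalog (code -> agent, route, MCL-treatment / corticosteroid flags),
* adverse-event (AE) diagnosis-code lists, one per AE category,
* the mantle-cell-lymphoma (MCL) diagnosis-code prefixes,
* comorbidity code lists, the Charlson Comorbidity Index (CCI) mapping and an
  atrial-fibrillation (AF) risk-factor model, and
* Consumer Price Index factors used to express costs in reference-year dollars.

All diagnosis-code matching is *prefix* based on normalized codes (dots
stripped, uppercased), because claims dialects disagree on dot placement and
family-level codes ("200.x") are the natural unit for this analysis.

The shipped default lists are illustrative synthetic stand-ins and are NOT
clinically validated; analyses of real data must supply their own lists.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from pydantic import BaseModel, field_validator, model_validator

__all__ = [
    "DrugEntry",
    "DrugCatalog",
    "AECategory",
    "AECodeSet",
    "CPITable",
    "CCICondition",
    "AFRiskModel",
    "CodeSets",
    "normalize_code",
    "load_codesets",
    "default_codesets",
    "classify_claim",
]

REFERENCE_YEAR = 2017


def normalize_code(code: str) -> str:
    """Normalize a diagnosis/procedure/drug code: strip dots, uppercase."""
    return str(code).replace(".", "").replace(" ", "").upper()


class DrugEntry(BaseModel):
    """One drug or administration code in the catalog."""

    code: str
    agent: str
    route: str  # "oral" | "infusion"
    is_mcl_treatment: bool = True
    is_corticosteroid: bool = False

    @field_validator("route")
    @classmethod
    def _route_known(cls, v: str) -> str:
        if v not in ("oral", "infusion"):
            raise ValueError(f"route must be 'oral' or 'infusion', got {v!r}")
        return v

    @field_validator("code")
    @classmethod
    def _norm(cls, v: str) -> str:
        return normalize_code(v)


class DrugCatalog(BaseModel):
    entries: list[DrugEntry]

    @model_validator(mode="after")
    def _unique_codes(self) -> "DrugCatalog":
        seen: dict[str, str] = {}
        for e in self.entries:
            if e.code in seen:
                raise ValueError(
                    f"duplicate drug code {e.code!r} listed under agents "
                    f"{seen[e.code]!r} and {e.agent!r}"
                )
            seen[e.code] = e.agent
        return self

    def lookup(self, code: str) -> DrugEntry | None:
        return self._by_code().get(normalize_code(code))

    def _by_code(self) -> dict[str, DrugEntry]:
        cache = getattr(self, "_code_cache", None)
        if cache is None:
            cache = {e.code: e for e in self.entries}
            object.__setattr__(self, "_code_cache", cache)
        return cache

    def agents(self) -> set[str]:
        return {e.agent for e in self.entries}


class AECategory(BaseModel):
    """Diagnosis-code prefixes defining one adverse-event category."""

    prefixes: list[str]
    exclude_prefixes: list[str] = []
    # rule "two_claims_7d": >=2 claims of the same cancer family >=7 days apart
    rule: str | None = None

    @field_validator("prefixes", "exclude_prefixes")
    @classmethod
    def _norm(cls, v: list[str]) -> list[str]:
        return [normalize_code(c) for c in v]

    @model_validator(mode="after")
    def _nonempty(self) -> "AECategory":
        if not self.prefixes:
            raise ValueError("AE category must have at least one code prefix")
        return self


class AECodeSet(BaseModel):
    categories: dict[str, AECategory]

    @model_validator(mode="after")
    def _check(self) -> "AECodeSet":
        if not self.categories:
            raise ValueError("ae_codes: empty categories map")
        sm = self.categories.get("secondary_malignancy")
        if sm is not None and not sm.exclude_prefixes:
            raise ValueError(
                "secondary_malignancy requires exclusion code prefixes "
                "(unspecified lymphoid/hematopoietic neoplasm families)"
            )
        return self


class CPITable(BaseModel):
    """Year -> multiplicative inflation factor to reference-year (2017) USD."""

    factors: dict[int, float]
    reference_year: int = REFERENCE_YEAR

    @model_validator(mode="after")
    def _check(self) -> "CPITable":
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("CPI factors must be positive")
        ref = self.factors.get(self.reference_year)
        if ref is None or abs(ref - 1.0) > 1e-9:
            raise ValueError(
                f"CPI factor for reference year {self.reference_year} must be 1.0"
            )
        return self

    def factor(self, year: int) -> float:
        try:
            return self.factors[year]
        except KeyError:
            raise KeyError(f"no CPI factor for service year {year}") from None


class CCICondition(BaseModel):
    weight: int
    prefixes: list[str]

    @field_validator("prefixes")
    @classmethod
    def _norm(cls, v: list[str]) -> list[str]:
        return [normalize_code(c) for c in v]


class AFRiskModel(BaseModel):
    """Config-driven point score for atrial-fibrillation risk.

    Each factor contributes ``points`` when >=1 baseline claim matches one of
    its prefixes; total points >= ``threshold`` classifies the patient
    high-risk.  The shipped default is illustrative, not a published model.
    """

    factors: dict[str, dict]
    threshold: int

    @model_validator(mode="after")
    def _check(self) -> "AFRiskModel":
        for name, f in self.factors.items():
            if "points" not in f or "prefixes" not in f or not f["prefixes"]:
                raise ValueError(f"af_risk factor {name!r} needs points and prefixes")
            f["prefixes"] = [normalize_code(c) for c in f["prefixes"]]
        return self


class CodeSets(BaseModel):
    """The full validated configuration bundle."""

    drug_catalog: DrugCatalog
    ae_codes: AECodeSet
    mcl_dx_prefixes: list[str] = ["200", "C831"]
    comorbidity_codes: dict[str, list[str]] = {}
    cci: dict[str, CCICondition] = {}
    af_risk: AFRiskModel | None = None
    cpi: CPITable

    @field_validator("mcl_dx_prefixes")
    @classmethod
    def _norm(cls, v: list[str]) -> list[str]:
        if not v:
            return ["200", "C831"]
        return [normalize_code(c) for c in v]

    @model_validator(mode="after")
    def _norm_comorb(self) -> "CodeSets":
        self.comorbidity_codes = {
            k: [normalize_code(c) for c in v] for k, v in self.comorbidity_codes.items()
        }
        return self


def _parse_raw(raw: dict) -> CodeSets:
    cpi_raw = raw.get("cpi", {})
    cpi = CPITable(factors={int(k): float(v) for k, v in cpi_raw.items()})
    ae = AECodeSet(
        categories={
            name: (AECategory(**spec) if isinstance(spec, dict) else AECategory(prefixes=spec))
            for name, spec in raw.get("ae_codes", {}).items()
        }
    )
    return CodeSets(
        drug_catalog=DrugCatalog(entries=raw.get("drug_catalog", [])),
        ae_codes=ae,
        mcl_dx_prefixes=raw.get("mcl_dx_prefixes", ["200", "C831"]),
        comorbidity_codes=raw.get("comorbidity_codes", {}),
        cci={k: CCICondition(**v) for k, v in raw.get("cci", {}).items()},
        af_risk=AFRiskModel(**raw["af_risk"]) if raw.get("af_risk") else None,
        cpi=cpi,
    )


def load_codesets(path: str | Path) -> CodeSets:
    """Load and validate a JSON code-set configuration file."""
    with open(path) as fh:
        raw = json.load(fh)
    return _parse_raw(raw)


def default_codesets() -> CodeSets:
    """The packaged default configuration (illustrative synthetic code lists)."""
    text = resources.files("mclclaims.data").joinpath("default_codesets.json").read_text()
    return _parse_raw(json.loads(text))


def _matches(code: str, prefixes: Iterable[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def matches_category(code: str, cat: AECategory) -> bool:
    """Prefix match against a category, honoring its exclusion prefixes."""
    code = normalize_code(code)
    if _matches(code, cat.exclude_prefixes):
        return False
    return _matches(code, cat.prefixes)


def classify_claim(claim: Mapping, codesets: CodeSets) -> set[str]:
    """Classify one claim into zero or more category labels.

    ``claim`` needs ``dx_codes`` (list or ';'-joined string, may be empty) and
    optionally ``code`` (drug/procedure code).  Labels: ``mcl_treatment``,
    ``mcl_dx``, ``ae:<name>``, ``comorbidity:<name>``; a claim matching nothing
    is labeled ``other``.  Matching is prefix-based and order-independent.
    """
    labels: set[str] = set()
    dx = claim.get("dx_codes") if hasattr(claim, "get") else getattr(claim, "dx_codes", None)
    if dx is None:
        dx = []
    if isinstance(dx, str):
        dx = [c for c in dx.split(";") if c]
    dx = [normalize_code(c) for c in dx]

    code = claim.get("code") if hasattr(claim, "get") else getattr(claim, "code", None)
    if code:
        entry = codesets.drug_catalog.lookup(code)
        if entry is not None and entry.is_mcl_treatment:
            labels.add("mcl_treatment")

    for c in dx:
        if _matches(c, codesets.mcl_dx_prefixes):
            labels.add("mcl_dx")
        for name, cat in codesets.ae_codes.categories.items():
            if matches_category(c, cat):
                labels.add(f"ae:{name}")
        for name, prefixes in codesets.comorbidity_codes.items():
            if _matches(c, prefixes):
                labels.add(f"comorbidity:{name}")
    if not labels:
        labels.add("other")
    return labels
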