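"""Adjusted first-line models: hospitalization risk and PPPM cost.

Among patients whose *first-line* regimen is one of the most common regimens,
two models quantify the burden of incident adverse events:

* logistic regression of any hospitalization during follow-up — exponentiated
  coefficients are odds ratios (OR);
* a generalized linear model with log link and gamma family for all-cause
  cost PPPM — exponentiated coefficients are cost ratios (CR).

Covariates: age at index (continuous), geographic region, insurance plan
type, CCI score (continuous), AF-risk status, baseline condition flags
(infection, hypertension, anemia, fatigue/asthenia, hemorrhage/bleeding,
AF), treatment regimen, and the AE exposure — either the number of incident
AEs (continuous, the default) or one indicator per AE of interest (fit
separately per AE).  Reference levels default to the modal categories
(South / PPO / R-CHOP) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ModelSpec", "FitResult", "build_first_line_frame",
           "fit_hospitalization_logit", "fit_cost_glm"]

BASELINE_FLAGS = (
    "comorb_infection", "comorb_hypertension", "comorb_anemia",
    "comorb_fatigue_asthenia", "comorb_hemorrhage_bleeding",
    "comorb_atrial_fibrillation",
)

COST_FLOOR = 0.01  # gamma support excludes zero; zero-cost patients get 1 cent


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "any_hospitalization"  # or "cost_pppm"
    ae_param: str = "count"  # "count" | "indicators"
    ae_indicator: str | None = None  # AE name when ae_param == "indicators"
    ref_region: str = "South"
    ref_plan: str = "PPO"
    ref_regimen: str = "R-CHOP"
    baseline_flags: tuple[str, ...] = BASELINE_FLAGS

    def __post_init__(self):
        if self.ae_param not in ("count", "indicators"):
            raise ValueError("ae_param must be 'count' or 'indicators'")
        if self.ae_param == "indicators" and not self.ae_indicator:
            raise ValueError("ae_param='indicators' needs ae_indicator")


@dataclass
class FitResult:
    outcome: str
    n: int
    converged: bool
    deviance: float | None
    table: pd.DataFrame  # term, coef, ratio, ci_low, ci_high, p

    def ratio(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "ratio"])

    def ci(self, term: str) -> tuple[float, float]:
        r = self.table.set_index("term").loc[term]
        return float(r["ci_low"]), float(r["ci_high"])


def build_first_line_frame(
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    episodes_by_patient: dict,
    pppm: pd.DataFrame,
    burden: pd.DataFrame,
    top_regimens: list[str],
    incident_aes: list | None = None,
) -> pd.DataFrame:
    """Analysis frame for the adjusted models (first-line setting).

    Keeps analyzed patients whose line-1 regimen is in ``top_regimens``.
    When ``incident_aes`` is given, adds one 0/1 column ``ae_<name>`` per
    observed AE category for the per-AE model variants.
    """
    line1 = {
        pid: eps[0].label
        for pid, eps in episodes_by_patient.items()
        if eps and eps[0].line == 1
    }
    df = profiles.merge(pppm, on="patient_id").merge(
        burden[["patient_id", "ae_count"]], on="patient_id"
    )
    df["regimen"] = df["patient_id"].map(line1)
    df = df[df["regimen"].isin(top_regimens)].reset_index(drop=True)
    df["any_hospitalization"] = df["all_any_hospitalization"].astype(int)
    df["cost_pppm"] = df["all_total_cost_pppm"]
    if incident_aes is not None:
        names = sorted({a.ae for a in incident_aes})
        have = {(a.patient_id, a.ae) for a in incident_aes}
        for name in names:
            df[f"ae_{name}"] = [
                int((pid, name) in have) for pid in df["patient_id"]
            ]
    return df


def _design(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["age"] = df["age_at_index"].astype(float)
    X["cci"] = df["cci"].astype(float)
    X["af_high"] = (df["af_risk"] == "high").astype(float)
    for flag in spec.baseline_flags:
        if flag in df:
            X[flag] = df[flag].astype(float)
    for col, ref in (("region", spec.ref_region), ("plan_type", spec.ref_plan),
                     ("regimen", spec.ref_regimen)):
        counts = df[col].astype(str).value_counts()
        for level in sorted(df[col].astype(str).unique()):
            # levels too sparse to estimate merge into the reference
            if level != ref and counts[level] >= 10:
                X[f"{col}[{level}]"] = (df[col].astype(str) == level).astype(float)
    if spec.ae_param == "count":
        X["ae_count"] = df["ae_count"].astype(float)
        exposure = ["ae_count"]
    else:
        col = f"ae_{spec.ae_indicator}"
        X[col] = df[col].astype(float)
        exposure = [col]
    return X, exposure


def _result_table(res, terms) -> pd.DataFrame:
    ci = res.conf_int()
    return pd.DataFrame({
        "term": terms,
        "coef": np.asarray(res.params, dtype=float),
        "ratio": np.exp(np.asarray(res.params, dtype=float)),
        "ci_low": np.exp(np.asarray(ci)[:, 0]),
        "ci_high": np.exp(np.asarray(ci)[:, 1]),
        "p": np.asarray(res.pvalues, dtype=float),
    })


def fit_hospitalization_logit(df: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Maximum-likelihood logistic fit of any-hospitalization.

    Non-convergence (for example complete separation) is surfaced through the
    ``converged`` flag rather than silently dropped.
    """
    spec = spec or ModelSpec(outcome="any_hospitalization")
    X, _ = _design(df, spec)
    y = df["any_hospitalization"].astype(float)
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:
        res = model.fit(disp=0, maxiter=200, method="bfgs")
        converged = False
    return FitResult(
        outcome="any_hospitalization",
        n=len(df),
        converged=converged,
        deviance=float(-2 * res.llf),
        table=_result_table(res, list(X.columns)),
    )


def fit_cost_glm(df: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Gamma GLM with log link for all-cause cost PPPM.

    Zero costs (possible in synthetic data) are floored at $0.01 before
    fitting; any remaining non-positive outcome is an error.
    """
    spec = spec or ModelSpec(outcome="cost_pppm")
    X, _ = _design(df, spec)
    y = df["cost_pppm"].astype(float).clip(lower=COST_FLOOR)
    if (y <= 0).any():
        raise ValueError("non-positive cost outcomes after flooring")
    if y.nunique() == 1:
        # degenerate outcome: the mean model is exact, every ratio is 1
        coefs = np.zeros(X.shape[1])
        coefs[list(X.columns).index("const")] = np.log(float(y.iloc[0]))
        table = pd.DataFrame({
            "term": list(X.columns), "coef": coefs, "ratio": np.exp(coefs),
            "ci_low": np.exp(coefs), "ci_high": np.exp(coefs),
            "p": np.full(X.shape[1], np.nan),
        })
        return FitResult(outcome="cost_pppm", n=len(df), converged=True,
                         deviance=0.0, table=table)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    return FitResult(
        outcome="cost_pppm",
        n=len(df),
        converged=bool(res.converged),
        deviance=float(res.deviance),
        table=_result_table(res, list(X.columns)),
    )
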