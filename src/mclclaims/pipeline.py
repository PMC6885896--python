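"""End-to-end orchestration: claims -> cohort -> episodes -> AEs -> tables -> fits.

``run_pipeline`` wires every stage together and (optionally) writes the
artifact bundle: the cohort and its attrition ledger, the episode table, the
incident-AE table and burden strata, the four analysis-table analogues
(baseline characteristics, incident AEs by regimen, PPPM utilization and
costs by AE-burden stratum), the first-line regimen distribution, and the
adjusted model fits.  Runs are deterministic given the configuration; the
configuration is serialized alongside the outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import adverse_events as ae_mod
from . import baseline as baseline_mod
from . import models as models_mod
from .claims import read_tables, treatment_events, write_tables
from .codesets import CodeSets, default_codesets, load_codesets
from .cohort import CohortParams, apply_attrition, restrict_to_top_regimens
from .episodes import EpisodeParams, build_episodes
from .synthetic import GeneratorConfig, SyntheticClaims, generate
from .utilization import pppm_stratum_table, summarize_pppm

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "summarize_baseline"]


@dataclass
class RunConfig:
    claims_dir: str | None = None  # read claims from CSVs; None -> synthesize
    codes_path: str | None = None  # None -> packaged defaults
    out_dir: str | None = None
    seed: int = 0
    n_patients: int = 200
    generator: GeneratorConfig | None = None
    episode_params: EpisodeParams = field(default_factory=EpisodeParams)
    cohort_params: CohortParams = field(default_factory=CohortParams)
    top_k: int = 4
    fit_models: bool = True


@dataclass
class PipelineResult:
    codesets: CodeSets
    tables: dict
    truth: dict | None
    cohort: pd.DataFrame
    analytic_cohort: pd.DataFrame
    attrition: list
    episodes_by_patient: dict
    top_regimens: list
    first_line_distribution: pd.DataFrame
    profiles: pd.DataFrame
    incident_aes: list
    burden: pd.DataFrame
    ae_table: pd.DataFrame
    pppm: pd.DataFrame
    stratum_table: pd.DataFrame
    baseline_table: pd.DataFrame
    fits: dict


def summarize_baseline(profiles: pd.DataFrame) -> pd.DataFrame:
    """Tidy baseline-characteristics table (counts/% and mean/SD/median)."""
    n = len(profiles)
    rows = []

    def cont(name, series):
        s = series.dropna()
        rows.append({
            "measure": name, "level": "", "n": None, "denominator": n,
            "pct": np.nan, "mean": float(s.mean()) if len(s) else np.nan,
            "sd": float(s.std(ddof=1)) if len(s) > 1 else np.nan,
            "median": float(s.median()) if len(s) else np.nan,
        })

    def cat(name, series):
        for level, k in series.value_counts().sort_index().items():
            rows.append({
                "measure": name, "level": str(level), "n": int(k),
                "denominator": n, "pct": 100.0 * k / n if n else np.nan,
                "mean": np.nan, "sd": np.nan, "median": np.nan,
            })

    cont("age_at_index", profiles["age_at_index"])
    cat("gender", profiles["gender"])
    cat("region", profiles["region"])
    cat("plan_type", profiles["plan_type"])
    cont("cci", profiles["cci"])
    cat("af_risk", profiles["af_risk"])
    cont("pill_burden", profiles["pill_burden"])
    cont("baseline_cost_pppm", profiles["baseline_cost_pppm"])
    for col in sorted(c for c in profiles.columns if c.startswith("comorb_")):
        k = int(profiles[col].sum())
        rows.append({
            "measure": col, "level": "yes", "n": k, "denominator": n,
            "pct": 100.0 * k / n if n else np.nan,
            "mean": np.nan, "sd": np.nan, "median": np.nan,
        })
    return pd.DataFrame(rows)


def _episodes_frame(episodes_by_patient: dict) -> pd.DataFrame:
    rows = []
    for pid in sorted(episodes_by_patient):
        for ep in episodes_by_patient[pid]:
            rows.append({
                "patient_id": pid, "line": ep.line, "label": ep.label,
                "agents": "+".join(sorted(ep.regimen)), "start": ep.start,
                "end": ep.end, "end_reason": ep.end_reason,
                "rituximab_modified": ep.rituximab_modified,
                "has_corticosteroid": ep.has_corticosteroid,
                "ae_reportable": ep.ae_reportable,
            })
    return pd.DataFrame(rows, columns=[
        "patient_id", "line", "label", "agents", "start", "end", "end_reason",
        "rituximab_modified", "has_corticosteroid", "ae_reportable",
    ])


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    cfg = config or RunConfig()
    codesets = load_codesets(cfg.codes_path) if cfg.codes_path else default_codesets()

    truth = None
    if cfg.claims_dir is not None:
        tables = read_tables(cfg.claims_dir)
    else:
        gen_cfg = cfg.generator or GeneratorConfig(
            n_patients=cfg.n_patients, seed=cfg.seed
        )
        synth: SyntheticClaims = generate(gen_cfg, codesets)
        tables = {
            "enrollment": synth.enrollment,
            "medical": synth.medical,
            "pharmacy": synth.pharmacy,
        }
        truth = synth.truth

    events = treatment_events(tables["medical"], tables["pharmacy"], codesets)
    cohort, attrition = apply_attrition(
        tables["enrollment"], tables["medical"], tables["pharmacy"],
        events, codesets, cfg.cohort_params,
    )

    episodes_by_patient = {}
    for rec in cohort.itertuples(index=False):
        pid = str(rec.patient_id)
        evs = [e for e in events.get(pid, []) if e.date >= rec.index_date]
        episodes_by_patient[pid] = build_episodes(
            evs, rec.censor_date, cfg.episode_params
        )

    # first-line regimen distribution among all treated, classified patients
    line1 = [eps[0].label for eps in episodes_by_patient.values() if eps]
    fl = pd.Series(line1).value_counts().sort_index()
    first_line = pd.DataFrame({
        "regimen": fl.index, "n": fl.values,
        "denominator": len(line1),
        "pct": 100.0 * fl.values / len(line1) if len(line1) else np.nan,
    })

    analytic, top, extra_ledger = restrict_to_top_regimens(
        cohort, episodes_by_patient, cfg.top_k
    )
    attrition = attrition + extra_ledger
    analytic_pids = set(analytic["patient_id"].astype(str))
    episodes_by_patient = {
        pid: eps for pid, eps in episodes_by_patient.items() if pid in analytic_pids
    }

    profiles = baseline_mod.baseline_profiles(
        analytic, tables["medical"], tables["pharmacy"], codesets,
        baseline_days=cfg.cohort_params.baseline_days,
    )

    excluded = set(
        analytic.loc[analytic["excluded_from_outcomes"].astype(bool), "patient_id"]
        .astype(str)
    )
    incident_aes = ae_mod.detect_incident_aes(
        tables["medical"], episodes_by_patient, codesets, excluded
    )
    analyzed_pids = sorted(analytic_pids - excluded)
    burden = ae_mod.assign_burden_strata(incident_aes, analyzed_pids)
    ae_table = ae_mod.ae_table_by_regimen(incident_aes, {
        pid: eps for pid, eps in episodes_by_patient.items() if pid not in excluded
    })
    pppm = summarize_pppm(tables["medical"], tables["pharmacy"], analytic, codesets)
    stratum_table = pppm_stratum_table(pppm, burden)
    baseline_table = summarize_baseline(profiles)

    fits: dict = {}
    if cfg.fit_models:
        frame = models_mod.build_first_line_frame(
            analytic, profiles, episodes_by_patient, pppm, burden, top
        )
        if len(frame) >= 50 and frame["any_hospitalization"].nunique() == 2:
            fits["hospitalization"] = models_mod.fit_hospitalization_logit(frame)
            fits["cost"] = models_mod.fit_cost_glm(frame)
            fits["_frame_n"] = len(frame)

    result = PipelineResult(
        codesets=codesets, tables=tables, truth=truth, cohort=cohort,
        analytic_cohort=analytic, attrition=attrition, episodes_by_patient=episodes_by_patient,
        top_regimens=top, first_line_distribution=first_line, profiles=profiles,
        incident_aes=incident_aes, burden=burden, ae_table=ae_table, pppm=pppm,
        stratum_table=stratum_table, baseline_table=baseline_table, fits=fits,
    )
    if cfg.out_dir is not None:
        _write_outputs(result, cfg)
    return result


def _fits_to_json(fits: dict) -> dict:
    out = {}
    for name, fr in fits.items():
        if name.startswith("_"):
            out[name] = fr
            continue
        out[name] = {
            "outcome": fr.outcome, "n": fr.n, "converged": fr.converged,
            "deviance": fr.deviance,
            "terms": {
                row["term"]: {
                    "ratio": row["ratio"], "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"], "p": row["p"],
                }
                for _, row in fr.table.iterrows()
            },
        }
    return out


def _write_outputs(res: PipelineResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.cohort.to_csv(out / "cohort.csv", index=False)
    _episodes_frame(res.episodes_by_patient).to_csv(out / "episodes.csv", index=False)
    pd.DataFrame(
        [dataclasses.asdict(a) for a in res.incident_aes]
    ).to_csv(out / "aes.csv", index=False)
    res.burden.to_csv(out / "burden.csv", index=False)
    res.baseline_table.to_csv(out / "table1_baseline.csv", index=False)
    res.ae_table.to_csv(out / "table2_aes.csv", index=False)
    res.stratum_table.to_csv(out / "table34_pppm_by_stratum.csv", index=False)
    res.first_line_distribution.to_csv(out / "first_line_regimens.csv", index=False)
    res.pppm.to_csv(out / "pppm_per_patient.csv", index=False)
    with open(out / "attrition.json", "w") as fh:
        json.dump(res.attrition, fh, indent=2)
    with open(out / "fits.json", "w") as fh:
        json.dump(_fits_to_json(res.fits), fh, indent=2)
    with open(out / "run_config.json", "w") as fh:
        json.dump(_config_json(cfg), fh, indent=2, default=str)


def _config_json(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
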