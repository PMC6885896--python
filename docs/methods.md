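# Methods

This note documents the models and procedures implemented in `mclclaims`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical and design decisions
taken where the underlying conventions are genuinely open.

## Study design emulated

The package implements a retrospective cohort analysis over adjudicated
administrative claims. The anchor is the **index date** — the first claim
for an MCL-directed systemic treatment inside the index window (default
2013-11-01 to 2017-12-31, inside a data window of 2012-11-01 to 2018-01-31).
Patients enter the cohort if they carry ≥ 1 MCL diagnosis (prefix families
`200` / `C83.1`, dots stripped) during the study period, are ≥ 18 at index,
have ≥ 12 months (implemented as 365 days) of continuous enrollment before
index and ≥ 30 days after, and have no MCL treatment during the 12-month
baseline. Patients indexed on ibrutinib with baseline treatment are retained
for baseline description but flagged `excluded_from_outcomes`, since
ibrutinib is indicated for previously treated disease; they contribute no
AEs, utilization or costs. Optional exclusions for baseline stem-cell
transplant and clinical-trial participation accept code-prefix lists and are
off by default (both are known to be under-coded in claims). After episode
construction, the analytic cohort keeps patients with ≥ 1 episode among the
k = 4 most common regimens across all observed lines (ranking by distinct
patient counts; ties break alphabetically; later-line rituximab monotherapy
counts toward rituximab monotherapy for ranking).

"Continuous" enrollment tolerates gaps of ≤ `enrollment_gap_tolerance` days
between spans (default 0, i.e. strict; 31 is a common claims convention).

## Episode rules and their edge cases

Parameters (all configurable via `EpisodeParams`):

| parameter | default | meaning |
|---|---|---|
| `window_days` | 35 | regimen-formation window, day 0 through day 34 inclusive |
| `gap_days` | 90 | coverage gap that constitutes discontinuation |
| `infusion_persist_days` | 30 | days an infusion claim is considered to provide treatment coverage |
| `oral_anchor` | `"supply"` | discontinuation end anchor for oral drugs: last covered day (`supply`) vs last fill date (`fill`) |

Decisions taken where the conventions are open:

- **Window boundary.** "The first 35 days" is closed on day 0..34; an agent
  first appearing on day 35 starts change evaluation (switch), not regimen
  membership.
- **Gap measurement** is supply-aware: from the end of drug coverage (fill +
  days supplied for oral; infusion date + 30), not from the last claim date.
  The discontinuation end date for oral regimens is the last covered day
  + 90 by default; a `fill` anchor (last fill date + 90) is exposed because
  the phrase "after the last prescription was supplied" is ambiguous.
- **Concomitant oral + infusion** regimens anchor the discontinuation end on
  the oral supply.
- **Switch-day ownership.** When a new agent appears, the entire calendar
  day belongs to the next episode: same-day claims for old-regimen agents
  join the *new* episode (whose 35-day window starts that day), and the old
  episode ends the day before. This keeps episodes tiling the treated
  timeline with every claim in exactly one episode.
- **Rituximab modifications.** Rituximab addition (a rituximab claim after
  the window when it was not in the regimen) and removal (its coverage
  lapsing while another regimen agent continues) never end an episode; both
  set `rituximab_modified`. Removal of a *non-rituximab* agent without any
  new agent does not end the episode either — only new agents and coverage
  gaps end it. The implementation reports a single `switch` end reason for
  any new-agent trigger; a "modification" of the starting regimen by a
  non-rituximab agent is observationally identical to a switch in claims, so
  the two are not separated.
- **Corticosteroids** never define regimen identity, never trigger switches,
  never provide coverage, and never index a patient; their presence in the
  window is kept as an annotation (`has_corticosteroid`).
- Line numbers are assigned by episode start order; the analysis focuses on
  lines 1–3 (`line_label` collapses later lines to "4+").

The episode builder is verified in two independent ways: against a literal
day-by-day simulation of the rules on randomized event sets, and against the
generator's embedded truth (exact recovery when enrollment churn and
pre-index treatment are disabled).

## Incident adverse events

Fifteen AE categories are tracked by diagnosis-code prefix lists. An AE is
incident when ≥ 1 in-episode claim exists and *no* claim for the category
precedes the episode's start. The look-back defaults to **all observable
history** ("no evidence prior to treatment initiation" read strictly); a
12-month-window variant is available (`lookback="baseline"`). An AE whose
first claim falls between episodes is not attributed to any episode.
Secondary malignancy requires ≥ 2 claims with the *same cancer* — the same
3-character code family by default (`same_cancer="exact"` available) —
≥ 7 days apart within one episode, with the unspecified
lymphoid/hematopoietic families (`202`, `C96`) excluded. A single earlier
claim of the same family blocks incidence. AE burden is the count of unique
incident categories over follow-up, stratified 0 / 1–2 / 3–5 / ≥ 6.

## Baseline measures

All baseline measures use claims strictly before index. The Charlson
Comorbidity Index uses a standard 17-condition/weight mapping shipped as
configuration data (abbreviated, illustrative code prefixes; users supply
their own dialect for real data). The AF-risk score is fully config-driven
(factor code lists, points, threshold) because the published risk model it
stands in for does not print reusable coefficients; the shipped default
(hypertension 1, diabetes 1, heart failure 2, obesity 1, sleep apnea 1,
threshold 2) is illustrative. Daily pill burden is total dispensed quantity
in the 30 days before index divided by 30, computed only for patients with
≥ 1 oral MCL-treatment fill. Baseline PPPM cost divides by exactly 12
months, since the cohort guarantees full baseline coverage.

## Utilization and costs

Claims are bucketed into hospitalization, ED, office, pharmacy and other
outpatient services. Outpatient medical claims carrying an MCL-treatment
administration code are counted under **pharmacy** (drug
acquisition/administration) together with dispensed prescriptions, mirroring
how claims analyses report "prescriptions/injection administrations" as one
drug category. Facility claims with overlapping inpatient spans form one
admission; length of stay is discharge − admit (minimum 1). An admission
counts as MCL-related if any claim in its bundle is; costs are subset at the
claim level. MCL-related means an MCL diagnosis at any position or an
MCL-treatment drug/procedure code. Money is held as integer cents after CPI
inflation to 2017 (rounding half away from zero; reversal amounts keep their
sign), so category costs sum to totals exactly. Follow-up months =
days / 30.4375.

## Adjusted models

Among patients whose first-line regimen is in the top four: logistic
regression of any hospitalization and a gamma GLM with log link for
all-cause cost PPPM (both via statsmodels; Gamma scale by Pearson χ²).
Covariates: age (continuous), region (ref South), plan type (ref PPO), CCI
(continuous), AF-risk status, six baseline condition flags, regimen (ref
R-CHOP), and the AE exposure — the incident-AE count entering linearly on
the link scale by default (a single reported OR/CR per unit implies a linear
term), or one indicator per AE fit separately. Categorical levels observed
fewer than 10 times merge into the reference to avoid separation. Zero-cost
outcomes are floored at $0.01 (gamma support excludes zero); a constant
outcome returns the exact degenerate fit. Non-convergence is surfaced via a
flag, never silently dropped.

Parameter recovery is demonstrated at a realistic scale: 200 replicates at
n = 1600 with a true cost ratio of 1.10 (gamma shape 2) and a true odds
ratio of 2.4 per AE; the mean fitted CR stays within 1.09–1.11, the mean OR
within 5% of truth, and 95% CI coverage within 90–98% for both.

## The synthetic generator

Defaults encode the study conditions the pipeline is meant to face: a
first-line regimen mix of R-CHOP 26%, rituximab monotherapy 19%, B-R 15%,
ibrutinib 5% and 35% other regimens (fragmented over five less common
regimens); a later-line mix favoring ibrutinib (30%), as in
relapsed/refractory practice; per-episode AE occurrence probabilities per
regimen patterned on the published toxicity profiles of R-CHOP, B-R and
ibrutinib (e.g. neutropenia 0.648 for R-CHOP); baseline comorbidity
prevalences patterned on a commercially insured MCL population (hypertension
0.397, anemia 0.323, …); per-line transition probabilities of 0.20 (switch)
and 0.15 (discontinue-then-restart); 10% enrollment churn; and 5% planted
pre-index treatment. Infusion regimens emit administration claims on 21-day
(R-CHOP, R-CVP) or 28-day (B-R, rituximab, R-BAC) cycles, weekly for
bortezomib; oral agents emit 30-day-supply fills (21 of 28 days for
lenalidomide) — schedules chosen so the 35-day window, 90-day gap and 30-day
persistence rules are all meaningful. One pseudo-random stream per patient
is keyed by `(seed, patient number)`, so a patient's record is invariant to
the cohort size.

Hospitalization is Bernoulli with logit = −1.5 + log(2.4)·(AE count); total
monthly cost is gamma (shape 2) with log-mean = log(11000) + log(1.1)·(AE
count) + small age/CCI/regimen effects, drawn per 30-day block and
distributed over that block's claims in exact cents (weights: inpatient 40,
drug claims 15, ED 5, others 1). The first MCL diagnosis is coded on the
index-date claim — diagnosis coding typically surfaces at treatment in
claims — which also keeps the *baseline* CCI low (median 0), matching the
young, low-comorbidity population profile the defaults target. The truth
record's blocked-AE bookkeeping accounts for cross-category code matches
(e.g. a baseline pneumonia claim blocks incident "infection").

What the generator does **not** emulate: duplicate/reversed claims, coding
errors or dialect drift, dose intensity, maintenance schedules, mortality,
or correlated comorbidity structure. Passing the recovery tests therefore
validates the algorithms under clean coding, not robustness of real-data
code lists — which is also why the shipped code lists are labeled
illustrative and real analyses must supply their own.

## Problem sizes and runtimes

The test suite exercises 200-patient end-to-end runs (plus one 2000-patient
run for the burden-gradient check and 2000 patients for mix calibration),
1000 randomized event sets against the day-by-day oracle, and 200-replicate
model-recovery studies at n = 1600. `scripts/acceptance.py` uses a
2000-patient cohort. These sizes give stable estimates (binomial/SE checks
use 3-SE bands) while keeping a full run in tens of seconds on one CPU.

## Known limitations

- Regimen labels cover the common MCL regimens; unmapped agent sets fall
  back to an `other:<agents>` label rather than a clinical classification.
- The incidence filter treats any prior claim as disqualifying evidence; it
  cannot distinguish history-of codes from active disease.
- The attrition cascade assumes one member id per patient (no probabilistic
  linkage or deduplication).
- Stem-cell-transplant analyses are out of scope; the transplant exclusion
  is a code-prefix hook only.
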