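"""Cohort attrition and incident adverse events, end to end.

Runs the inclusion/exclusion cascade (attrition ledger), restricts to the
four most common regimens, and tabulates incident AEs by regimen — an AE
counts only when it appears during a treatment episode with no earlier claim
for the same category anywhere in the observable history.
"""

from mclclaims import RunConfig, run_pipeline

res = run_pipeline(RunConfig(n_patients=400, seed=7, fit_models=False))

print("attrition cascade:")
for stage in res.attrition:
    print(f"  {stage['stage']:40s} {stage['n']:5d}")
print(f"\nfour most common regimens: {', '.join(res.top_regimens)}")

tab = res.ae_table.set_index(["regimen", "measure"])
for reg in ("R-CHOP", "B-R", "ibrutinib"):
    if (reg, "patients") not in tab.index:
        continue
    n = int(tab.loc[(reg, "patients"), "n"])
    ge1 = tab.loc[(reg, "ge1_ae")]
    print(f"{reg:10s} n={n:4d}  >=1 incident AE: {int(ge1['n']):4d} "
          f"({ge1['pct']:.1f}%)")
# The percentages are per-regimen toxicity burdens; denominators are patients
# with at least one episode of that regimen (later-line rituximab monotherapy
# is excluded — claims cannot separate it from maintenance).
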