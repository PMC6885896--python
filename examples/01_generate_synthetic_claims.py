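"""Generate a synthetic adjudicated-claims bundle with embedded ground truth.

The generator emulates a commercial claims extract: enrollment spans with
member demographics, medical claims (diagnoses, procedures, settings, allowed
amounts) and pharmacy claims (NDC, days supplied, quantity).  Every patient
carries a truth record — true treatment episodes, true incident AEs, true
cost model — so the analysis stages can be validated exactly.
"""

from mclclaims.synthetic import GeneratorConfig, generate

synth = generate(GeneratorConfig(n_patients=100, seed=42))

print(f"enrollment spans : {len(synth.enrollment):5d} rows")
print(f"medical claims   : {len(synth.medical):5d} rows")
print(f"pharmacy claims  : {len(synth.pharmacy):5d} rows")

pid = "P000001"
t = synth.truth[pid]
print(f"\npatient {pid}: age {t.age}, {t.region}, {t.plan_type}, CCI {t.cci}")
print(f"index {t.index_date}, censored {t.censor_date}")
for ep in t.episodes:
    print(f"  line {ep.line}: {ep.regimen_label:20s} {ep.start} -> {ep.end} "
          f"({ep.end_reason})")
print(f"incident AEs: {sorted(t.incident_aes) or 'none'}")
print(f"expected monthly cost: ${t.expected_monthly_cost:,.0f}")
# Each line above is a *true* quantity the pipeline should recover from the
# raw claims alone; the truth never feeds the analysis itself.
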