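"""Draw sampling designs and compose stabilized IPW with design weights.

A subcohort keeps every exposed subject (pi = 1) and a fraction f of the
unexposed (pi = f); a case-cohort additionally keeps every case at selection
weight 1.  The exposure model is weighted by 1/pi so it estimates the
full-cohort propensity, and the outcome-model weight is ipw / pi.
"""

import cohortsampling as cs
from cohortsampling import designs as dz

cohort = cs.simulate_cohort(cs.desk_scale(n=20_000), seed=1)

sub = dz.draw_subcohort(cohort, f=0.25, seed=7)
cc = dz.draw_case_cohort(cohort, f=0.25, seed=7)
print(f"cohort n={len(cohort)}, events={int(cohort['event'].sum())}")
print(f"subcohort members={len(sub)}")
print(f"case-cohort members={len(cc)} "
      f"(non-subcohort cases={int(cc.nonsubcohort_case.sum())})")

members = cc.members(cohort)
model = cs.fit_exposure_model(members, sampling_probs=cc.sampling_prob)
weights = cs.stabilized_ipw(members, model, sampling_probs=cc.sampling_prob)
print(f"\nexposure model converged in {model.n_iter} IRLS iterations "
      f"(grad norm {model.grad_norm:.2e})")
print("weight diagnostics (stabilized IPW should average ~1 per group):")
for key, stats in cs.weight_diagnostics(weights, members["exposure"].to_numpy()).items():
    print(f"  {key}: mean={stats['mean']:.3f} sd={stats['sd']:.3f} "
          f"min={stats['min']:.3f} max={stats['max']:.3f}")

rows = dz.build_analysis_rows(cohort, cc, weights, estimand="HR")
late = rows[cc.nonsubcohort_case]
print(f"\nnon-subcohort cases late-enter 0.001 py before their event, e.g.:")
print(late[["id", "start", "stop", "event", "weight"]].head(3).to_string(index=False))
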