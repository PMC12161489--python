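"""Survival stratification by hypoxia score.

Kaplan-Meier + log-rank comparison of the HS-high vs HS-low groups and
Cox proportional-hazards models, on a cohort with a planted hazard
increase per unit of latent hypoxia.
"""

import hypometab as hm

cohort = hm.generate_cohort(seed=1)
scores = hm.score_signature(cohort.expr)

for endpoint in ("os", "dss", "rfs"):
    time, event = cohort.clinical.endpoint(endpoint)
    grp = scores.table.loc[time.index, "group"]
    chi2, p = hm.logrank(time, event, grp)
    print(f"{endpoint.upper():>4}: log-rank chi2 = {chi2:6.2f}, p = {p:.2e}")
# HS-high patients fare consistently worse on every endpoint, because
# the generator plants an exponential hazard increasing with hypoxia.

time, event = cohort.clinical.endpoint("os")
design = hm.encode_covariates(cohort.clinical, scores)
design = design.loc[design.index.intersection(time.index)]
res = hm.cox_ph(time.loc[design.index], event.loc[design.index], design)
print(f"\nmultivariate Cox PH (OS), n = {res.n}, events = {res.n_events}, "
      f"converged = {res.converged}")
print(res.table.round(3).to_string())
# hs_high is the hazard ratio of the HS-high group adjusted for grade,
# stage and PAM50 label; a ratio above 1 with p < 0.05 marks hypoxia as
# an independent prognostic factor in this simulated cohort.
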