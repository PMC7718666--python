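"""Covariate-adjusted group comparison on a simulated three-group cohort.

The cohort generator plants known group effects on each OCTA metric (for
superficial vessel density: MCI -0.72, AD -0.88 versus control) plus
covariate structure; the adjusted linear model should recover them.
"""

from octaquant.stats import bonferroni_threshold, fit_adjusted_model
from octaquant.synthetic import CohortParams, generate_cohort

cohort, truth = generate_cohort(
    CohortParams(n_per_group={"AD": 200, "MCI": 200, "control": 200}, seed=1)
)
fit = fit_adjusted_model(cohort, "vd_scp")
threshold = bonferroni_threshold(0.05, 2)

print(f"n = {fit.n}, covariates adjusted: age, gender, race, diabetes, BP, signal strength")
for g in ("MCI", "AD"):
    lo, hi = fit.ci[g]
    flag = "*" if fit.p_value[g] < threshold else " "
    print(f"  {g:7s} beta {fit.beta[g]:+6.3f}  (95% CI {lo:+.3f} to {hi:+.3f})  "
          f"p = {fit.p_value[g]:.4f}{flag}  planted {truth['group_effects']['vd_scp'][g]:+.2f}")
print(f"adjusted means: " + ", ".join(f"{g} {m:.2f}" for g, m in fit.adjusted_mean.items()))
print(f"Bonferroni threshold for the two primary outcomes: {threshold}")

# The group coefficient equals the adjusted-mean difference exactly; with
# n=200/group both planted effects are recovered well inside their CIs.
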