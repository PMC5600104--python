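"""One-sample MR on a synthetic biobank-style cohort.

Generates a confounded cohort with a known (null) causal effect, scores
individuals with a weighted genetic risk score, and contrasts the biased
observational regression with the MR estimate.
"""

from mrkinetics import (OneSampleConfig, compute_grs, filter_analysis_sample,
                        instrument_strength, observational_association,
                        one_sample_mr)
from mrkinetics.simulate import CohortSpec, generate_cohort

spec = CohortSpec(n=8072, beta_causal=0.0, seed=2026)
cohort = filter_analysis_sample(generate_cohort(spec))
print(f"analysis sample: {cohort.n} coffee-drinking daily smokers")

scores = compute_grs(cohort)  # external per-allele weights (cups/day)
f_stat, r2 = instrument_strength(scores, cohort.exposure,
                                 cohort.covariates[["age", "sex"]])
print(f"genetic risk score: F = {f_stat:.1f}, incremental R^2 = {r2:.4f}")

obs_beta, obs_se = observational_association(cohort, adjustments=("age", "sex"))
mr = one_sample_mr(cohort, OneSampleConfig(covariates=("age", "sex"), seed=1))
print(f"observational slope: {obs_beta:5.2f} (robust SE {obs_se:.2f})")
print(f"MR estimate:         {mr.estimate:5.2f} "
      f"95% CI ({mr.ci_low:.2f}, {mr.ci_high:.2f})")
print(f"true causal effect:  {cohort.true_params['beta_causal']:.2f}; "
      f"expected confounding bias {cohort.true_params['observational_bias']:.2f}")
print("\nThe observational slope reproduces the built-in confounding almost "
      "exactly, while the MR interval is centred near the true (null) effect "
      "— though wide, because the per-allele effects are small.")
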