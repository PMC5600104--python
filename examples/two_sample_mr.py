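"""Two-sample MR of coffee consumption on smoking heaviness.

Loads the packaged per-SNP summary tables (coffee exposure from a consumer
GWAS replication sample; cigarettes/day outcome from a tobacco consortium),
harmonizes them, and combines per-SNP Wald ratios by fixed-effects IVW and
the pleiotropy-robust weighted median.
"""

from mrkinetics import MRConfig, forest_table, load_instrument_set, run_two_sample_mr

iset = load_instrument_set("tag_cigarettes")
config = MRConfig(models=("8-SNP", "6-SNP", "2-SNP"),
                  methods=("IVW-FE",), seed=1)
results = run_two_sample_mr(iset, config)

print("Causal effect of coffee on smoking (cigarettes/day per cup/day):")
for model, res in zip(config.models, results):
    print(f"  {model:>5} IVW   beta = {res.estimate:6.2f}  "
          f"95% CI ({res.ci_low:5.2f}, {res.ci_high:5.2f})  p = {res.p:.3f}")

wm = run_two_sample_mr(iset, MRConfig(models=("8-SNP",),
                                      methods=("weighted-median",), seed=1))[0]
print(f"  8-SNP median beta = {wm.estimate:6.2f}  "
      f"95% CI ({wm.ci_low:5.2f}, {wm.ci_high:5.2f})")

print("\nPer-SNP forest table (8-SNP IVW):")
print(forest_table(results[0]).round(3).to_string(index=False))
print("\nNegative betas mean each extra daily cup of coffee predicts fewer "
      "cigarettes smoked per day; the weighted-median agreeing with IVW "
      "suggests the signal is not driven by a single pleiotropic SNP.")
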