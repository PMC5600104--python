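"""Analytic power of an MR design with a continuous exposure and outcome.

Evaluates the closed-form power for a biobank-scale sample (n = 8072,
exposure SD 2 cups/day, outcome SD 8.5 cigarettes/day) to detect a causal
effect of 1.5 cigarettes/day per cup/day, across instrument strengths.
"""

from mrkinetics import PowerSpec, mr_power, mr_power_curve

spec = PowerSpec(n=8072, r_squared=0.005, beta=1.5, sd_x=2.0, sd_y=8.5)
print(f"power at R^2 = 0.5%: {100 * mr_power(spec):.0f}%")

curve = mr_power_curve(spec, "r_squared", [0.0025, 0.005, 0.0075, 0.01, 0.02])
curve["power_pct"] = (100 * curve["power"]).round(1)
print(curve[["r_squared", "power_pct"]].to_string(index=False))

print("\nWith the instrument explaining 0.5-1% of exposure variance the "
      "design has 61-89% power, so a true effect of -1.5 cigarettes/day per "
      "cup could plausibly be missed at the weaker end.")
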