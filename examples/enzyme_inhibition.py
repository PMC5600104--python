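"""CYP2A6 inhibition kinetics: Ki estimation, type classification, and a
physiological prediction.

Simulates a competitive-inhibition velocity assay (caffeic-acid-like
Ki = 152 uM) with 5% multiplicative noise, estimates Ki from Dixon plots,
classifies the inhibition type from the joint Dixon / Cornish-Bowden
geometry, checks for mechanism-based inhibition via pre-incubation, and
predicts the in-vivo fractional inhibition at plasma concentrations.
"""

from mrkinetics import (KineticParams, classify_inhibition, fit_dixon,
                        fractional_inhibition, mg_per_l_to_um,
                        preincubation_test, CAFFEIC_ACID_MW)
from mrkinetics.simulate import generate_kinetic_dataset

params = KineticParams.competitive(vmax=1.0, km=50.0, ki=152.0)
assay = generate_kinetic_dataset(
    params, substrate_uM=[25.0, 50.0, 100.0, 200.0],
    inhibitor_uM=[0.0, 50.0, 150.0, 300.0],
    cv=0.05, replicates=3, seed=11)

fit = classify_inhibition(assay)
print(f"inferred inhibition type: {fit.inferred_type}")
print(f"Dixon-plot Ki estimate:   {fit.ki:.0f} uM (truth 152 uM)")

pre = generate_kinetic_dataset(
    params, [25.0, 100.0], [0.0, 50.0, 150.0, 300.0], cv=0.05, replicates=3,
    preincubation_effect=1.0, include_preincubated=True, seed=12)
verdict = preincubation_test(pre.arm(False), pre.arm(True))
print(f"pre-incubation verdict:   {verdict.verdict} (p = {verdict.p_value:.2f})")

plasma_um = mg_per_l_to_um(1.11, CAFFEIC_ACID_MW)
frac = fractional_inhibition(plasma_um, ki_uM=156.0)
print(f"plasma 1.11 mg/l = {plasma_um:.2f} uM "
      f"-> {100 * frac:.1f}% inhibition of nicotine metabolism")

print("\nA reversible competitive inhibitor with Ki in the hundreds of uM "
      "at low-uM plasma levels inhibits only a few percent of CYP2A6 "
      "activity — far too little to change smoking behaviour.")
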