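"""Dose-volume histogram indices for one plan.

Generates a phantom with a CTV-conformal dose distribution at a
5040 cGy prescription and reads the planning indices of record off the
DVH for the target and two organs at risk, with their constraint checks.
"""

import contoureval as ce

image, manual = ce.generate_phantom(seed=3)
plan = ce.PlanConfig()  # 5040 cGy in 28 fractions, standard constraint set
dose = ce.synth_dose(manual, plan, seed=4)

for name, metrics in (("CTV", ("Dmean", "Dmax", "V100%", "D99%")),
                      ("Bladder", ("Dmean", "D50%", "D0.03cc")),
                      ("Kidney L", ("Dmean",))):
    values = [f"{m}={ce.metric_value(m, dose, manual[name], plan):.1f}" for m in metrics]
    print(f"{name:10s} " + "  ".join(values))

table = ce.evaluate_dosimetry(dose, manual, manual, plan)
flags = table[table.constraint.notna() & (table.provenance == "manual")]
print(f"\nplan constraints satisfied: {int(flags.constraint_pass.sum())}/{len(flags)}")
print("(V100% is the percent of the target covered by the prescription isodose;")
print(" Dx% is the minimum dose to the hottest x% of the structure, in cGy)")
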