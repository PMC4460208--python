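"""Generate a study-design dissolution dataset and inspect its shape.

Five extrudate formulations (diameters 0.6-3.5 mm), sampled every 5 min up
to 1000 min, with 1% Gaussian assay noise: 1000 records in total.
"""

import dissogp as dg

ds = dg.simulate_profiles(noise_sd=1.0, seed=0)
print(f"records: {len(ds)}  formulations: {ds.formulations}")
for spec in ds.formulation_specs():
    prof = ds.profile(spec.formulation_id)
    print(f"  {spec.formulation_id}: d={spec.d} mm  L={spec.L} mm  "
          f"Q(1000 min) = {prof['Q_pct'].iloc[-1]:6.2f} %")

folds = dg.split_leave_one_formulation_out(ds)
print(f"leave-one-formulation-out folds: {len(folds)} "
      f"(test fold = {len(folds[0].test)} records, "
      f"{100 * len(folds[0].test) // len(ds)}% of the data)")
# Thicker extrudates release slower: Q at the end of the run drops with d.
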