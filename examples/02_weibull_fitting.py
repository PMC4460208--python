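"""Fit the Weibull release model to each formulation's profile.

Q(t) = 100*(1 - exp(-(t/A)^K)).  The time scale A is the 63.2%-release
time; the shape K controls the sigmoidicity.  One (A, K) pair per
formulation is the input table for indirect symbolic regression.
"""

import dissogp as dg

ds = dg.simulate_profiles(noise_sd=1.0, seed=0)
print(f"{'id':>4} {'d [mm]':>7} {'A [min]':>10} {'K':>7} {'RMSE [%]':>9}")
for spec in ds.formulation_specs():
    prof = ds.profile(spec.formulation_id)
    p, fit_rmse = dg.fit_weibull_profile(prof["t_min"], prof["Q_pct"])
    print(f"{spec.formulation_id:>4} {spec.d:7.1f} {p.A:10.1f} "
          f"{p.K:7.3f} {fit_rmse:9.3f}")
# A grows steeply with diameter (slower release from thicker extrudates);
# the fit RMSE ~ the 1% injected measurement noise.
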