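"""Dissociation-gated phosphorylation kinetics in solution.

Simulates the HPLC peak-area experiments (free switch peptide, and the
peptide complexed with either acidic partner) and the CD-monitored
reactions at 25 and 37 degC, fits every trace with the single-exponential
rise/decay models, and reports the stability- and concentration-dependence
of the observed rates.

Writes results/kinetics_timecourses.csv and results/kinetics_fits.csv.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from ccswitch import presets
from ccswitch.fitting import fit_decay, fit_rise
from ccswitch.kinetics import effective_rate
from ccswitch.synth import NoiseModel, SyntheticConfig, gen_cd_kinetic, gen_hplc

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SEED = 31

fits, traces = [], []

# --- HPLC experiments -------------------------------------------------------
for preset, label in [("hplc_free_25C", "B_RRS alone"),
                      ("hplc_AS_25C", "B_RRS + A_S"),
                      ("hplc_AN4_25C", "B_RRS + A_N4")]:
    params, init, _ = presets.get_preset(preset)
    t = presets.preset_times(preset, 60)
    cfg = SyntheticConfig(mode="hplc", kinetic_params=params, init=init,
                          times=tuple(t),
                          noise=NoiseModel("multiplicative", 0.05), seed=SEED)
    tc = gen_hplc(cfg)
    k_prod = fit_rise(tc.times, tc["product_area"]).k
    k_subs = fit_decay(tc.times, tc["substrate_area"]).k
    fits.append(dict(experiment=label, observable="HPLC",
                     k_prod_per_min=k_prod, k_subs_per_min=k_subs))
    df = tc.to_frame()
    df.insert(0, "experiment", label)
    traces.append(df)

# --- CD experiments ---------------------------------------------------------
for preset, label in [("cd_AS_25C", "B_RRS + A_S, 25C"),
                      ("cd_AS_37C", "B_RRS + A_S, 37C")]:
    params, init, _ = presets.get_preset(preset)
    t = presets.preset_times(preset)
    cfg = SyntheticConfig(mode="cd_kinetic", kinetic_params=params, init=init,
                          times=tuple(t), noise=NoiseModel("gaussian", 0.02),
                          seed=SEED)
    tc = gen_cd_kinetic(cfg)
    fits.append(dict(experiment=label, observable="CD MRE222",
                     k_prod_per_min=fit_rise(tc.times, tc["mre222"]).k,
                     k_subs_per_min=float("nan")))

fit_df = pd.DataFrame(fits)
fit_df.to_csv(RESULTS / "kinetics_fits.csv", index=False)
pd.concat(traces).to_csv(RESULTS / "kinetics_timecourses.csv", index=False)

k_free = fit_df.loc[0, "k_prod_per_min"]
k_as = fit_df.loc[1, "k_prod_per_min"]
k_an4 = fit_df.loc[2, "k_prod_per_min"]
print("Fitted rates (min^-1):")
print(fit_df.to_string(index=False))
print(f"\nComplexation with A_S slows phosphorylation {k_free / k_as:.0f}-fold;"
      f" with the more stable A_N4 partner {k_free / k_an4:.0f}-fold"
      " (orders of magnitude), confirming that only the dissociated monomer"
      " is processed.")

p, init50, _ = presets.get_preset("hplc_AS_25C")
k50 = effective_rate(p, init50, times=presets.preset_times("hplc_AS_25C"))
k1 = effective_rate(p, presets.equilibrium_state(1.0, 1.0, p))
print(f"Diluting from 50 uM to 1 uM at fixed stability speeds the reaction "
      f"{k1 / k50:.1f}-fold (larger free-monomer pool).")

pl, initl, _ = presets.get_preset("partial_limiting_25C")
tl = presets.preset_times("partial_limiting_25C")
ratio = effective_rate(replace(pl, kinase_scale=3.0), initl, times=tl) / \
    effective_rate(pl, initl, times=tl)
print(f"Tripling the kinase in the slow-exchange regime raises the observed "
      f"rate only {ratio:.1f}-fold: monomer rebinding competes with "
      "phosphorylation.")
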