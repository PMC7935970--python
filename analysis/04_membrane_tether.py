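"""Reversible membrane tethering of a cargo peptide to an SLB anchor.

Generates a synthetic confocal z-stack time series of the anchor/cargo
system (kinase added at t = 0, phosphatase later), quantifies membrane
localization through the z-profile pipeline, fits the cargo release
kinetics, and compares pre/post-kinase membrane binding with the unpaired
two-tailed t test.

Writes results/tether_timecourse.csv and results/tether_quantitation.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ccswitch import presets
from ccswitch.fitting import fit_constant, fit_rise, unpaired_t_test
from ccswitch.imaging import peak_area, peak_intensity_timecourse, z_profile
from ccswitch.kinetics import Event
from ccswitch.synth import SyntheticConfig, gen_slb_series, tether_release_config

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SEED = 41

# release phase: kinase at t=0, then phosphatase at t=70 for reversibility
params, init, _ = presets.get_preset("tether_slb")
base = tether_release_config(seed=SEED, t_end=160.0, n_frames=64)
cfg = SyntheticConfig(**{**base.__dict__,
                         "events": (Event(0.0, kinase=1.0),
                                    Event(70.0, phosphatase=1.0))})
stack, truth = gen_slb_series(cfg)

cargo = peak_intensity_timecourse(stack, "cargo")
anchor = peak_intensity_timecourse(stack, "anchor")
release_mask = cargo.times <= 70.0
res = fit_rise(cargo.times[release_mask], cargo["peak_intensity"][release_mask])
k_anchor, se_anchor = fit_constant(anchor.times, anchor["peak_intensity"])

df = pd.DataFrame(dict(
    time_min=cargo.times, cargo_peak=cargo["peak_intensity"],
    anchor_peak=anchor["peak_intensity"],
    cargo_membrane_truth=truth["cargo_membrane"]))
df.to_csv(RESULTS / "tether_timecourse.csv", index=False)

# replicate pre/post-kinase peak-area quantitation (n = 3)
pre, post = [], []
for r in range(3):
    s, _ = gen_slb_series(tether_release_config(seed=SEED + 1 + r))
    pre.append(peak_area(z_profile(s, "cargo", 0)))
    post.append(peak_area(z_profile(s, "cargo", s.data.shape[0] - 1)))
t_res = unpaired_t_test(pre, post)
quant = pd.DataFrame(dict(replicate=[1, 2, 3], pre_kinase_area=pre,
                          post_kinase_area=post))
quant.to_csv(RESULTS / "tether_quantitation.csv", index=False)

low = cargo["peak_intensity"][(cargo.times > 50) & (cargo.times <= 70)].min()
final = cargo["peak_intensity"][-1]
print(f"Cargo release after kinase: k = {res.k:.3f} min^-1 "
      "(generator calibrated to 0.07).")
print(f"Anchor channel constant fit: {k_anchor:.0f} +/- {se_anchor:.0f} "
      "intensity units (membrane anchor stays put).")
print(f"Phosphatase at t = 70 min rebinds the cargo: peak intensity rises "
      f"from {low:.0f} back to {final:.0f}.")
print(f"Membrane binding pre vs post kinase (n = 3 peak areas): "
      f"t = {t_res.t:.1f}, p = {t_res.p:.2g} (synthetic replicate scatter is "
      "far tighter than experimental).")
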