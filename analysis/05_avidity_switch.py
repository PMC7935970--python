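"""MinD-mimicking avidity switch on supported lipid bilayers.

Either switch protein alone binds the membrane negligibly through its
single weak membrane-targeting sequence; the heterodimer holds on with two
and is retained.  Kinase addition dissolves the dimer through the
dissociation-gated pathway and both proteins leave the membrane; the
phosphatase partially restores binding.

Writes results/avidity_enrichment.csv and results/avidity_release.csv.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from ccswitch import presets
from ccswitch.fitting import fit_rise
from ccswitch.imaging import peak_intensity_timecourse
from ccswitch.synth import avidity_release_config, gen_slb_series

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SEED = 51

params, _, _ = presets.get_preset("avidity_slb")

rows = []
for label, a_tot, b_tot in [("SwitchA alone", 1.0, 0.0),
                            ("SwitchB alone", 0.0, 1.0),
                            ("both proteins", 1.0, 1.0)]:
    ss = presets.avidity_steady_state(params, a_tot, b_tot)
    rows.append(dict(
        condition=label,
        A_membrane_fraction=(ss.A_mem + ss.AB_mem) / max(a_tot, 1e-12)
        if a_tot else 0.0,
        B_membrane_fraction=(ss.B_mem + ss.AB_mem) / max(b_tot, 1e-12)
        if b_tot else 0.0))
enrich = pd.DataFrame(rows)
enrich.to_csv(RESULTS / "avidity_enrichment.csv", index=False)

stack, truth = gen_slb_series(avidity_release_config(seed=SEED))
release = {}
for channel in ("switchA", "switchB"):
    tc = peak_intensity_timecourse(stack, channel)
    release[channel] = fit_rise(tc.times, tc["peak_intensity"]).k
pd.DataFrame(dict(channel=list(release), k_release_per_min=list(release.values()))
             ).to_csv(RESULTS / "avidity_release.csv", index=False)

print("Steady-state membrane fractions (well-mixed proxy):")
print(enrich.to_string(index=False))
single = enrich.loc[0, "A_membrane_fraction"]
both = enrich.loc[2, "B_membrane_fraction"]
print(f"\nDimerization raises membrane binding {both / single:.1f}-fold over "
      "a single protein (avidity).")
print("Kinase-triggered release rates recovered through the imaging "
      "pipeline: " + ", ".join(f"{c}: {k:.3f} min^-1"
                               for c, k in release.items())
      + " (generator calibrated to 0.10).")
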