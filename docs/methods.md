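# Methods

This note documents the models implemented in `ccswitch`, their
assumptions and defaults, the calibrations behind the named presets, what
the synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## Sequence model

Heptad registers use the alphabet `abcdefg` with `register_offset = 0`
placing the first *core* residue at *a*; non-heptad caps and linkers are
declared as flanks and carry register `-`, excluded from wheel and pairing
logic but included in mass and extinction-coefficient arithmetic.  Kinase
motifs are grafted by anchoring the motif's last S/T at a requested
(register, heptad) position; `x` positions always keep the parent residue
(so the realized RRxS motif inherits its X from the parent sequence).

The bundled peptide set is a **synthetic reconstruction** built from the
design rules of this heterodimer family: acidic strand `IAALEQE`-type
heptads (E at *e*/*g*), basic strand `IAALKQK`-type heptads (K at
*e*/*g*), an Asn-Asn' pair at *a* of heptad 4 to fix register and
orientation, the RRxS graft (Ser at *a2*, Arg-Arg at *e1*/*f1*) on the
basic strand, and the Ile->Ser substitution at *a2'* of the acidic
partner.  Gly/Trp caps with acetyl/amide termini are included.  The
fusion-protein records use a generic beta-barrel-sized fluorescent-protein
placeholder and are labelled stand-ins; their masses exercise the mass
engine but are not reference values.

Masses are computed from residue elemental formulas with IUPAC 2021
average atomic weights (monoisotopic available); modification deltas:
acetyl +42.037, C-terminal amide -0.985, phospho +79.979 Da; free termini
add one water.  Because the expected/observed masses of fusion constructs
in this field are often reported without stating N-terminal Met
processing, mass comparisons report both Met-retained and Met-cleaved
values.  Extinction coefficients use eps280 = 5690/Trp + 1280/Tyr
M^-1 cm^-1.

Helical wheels use the coiled-coil periodicity of 3.5 residues/turn
(102.857 deg/residue, exactly 720/7) so register positions of successive
heptads superimpose; the hydrophobic moment uses the same step and the
Eisenberg consensus scale by default, making homopolymer moments vanish
over whole heptads.

## Pairing energies

The a-a' pairing table ships as a CSV of relative coupling energies
(kcal/mol).  Only the ordinal structure is contractual - Ile-Ile is the
most stabilizing pair, Ser-Ile the least destabilizing substitution, and
Ser prefers homotypic Ser-Ser among polar partners - because no absolute
coupling energies are published for this set; the numbers are
order-calibrated placeholders a user can replace.

## Two-state dimer thermodynamics

Thermal melts model the equimolar heterodimer A + B <=> AB with

    Kd(T) = (Ctot/4) * exp(-dH/R * (1/T - 1/Tm)),

which makes the fraction folded exactly 0.5 at `Tm` for total peptide
concentration `Ctot` (default 100 uM, i.e. 50 uM per strand - the CD
condition).  `dH` is the van 't Hoff dissociation enthalpy, default 40
kcal/mol, a typical value for a four-heptad dimer; no dCp term.  The CD
observable interpolates between folded (-33,000) and unfolded (-3,000 deg
cm^2 dmol^-1) MRE222 baselines, optionally sloped.

**Tm extraction.**  The instrument-style procedure takes the second
derivative of the melt curve (Savitzky-Golay, cubic, window 5-11 points
auto-scaled to the grid, edges excluded from lobe detection) and uses the
zero crossing between its two lobes to locate the transition; absence of
two clear lobes is an explicit no-call.  For a *bimolecular* two-state
melt this landmark sits 1.5-2 degC above the half-folded temperature at
realistic enthalpies (the curve is asymmetric), so the landmark then seeds
a fit of the two-state dimer model itself - whose normalized shape depends
only on (Tm, dH), hence needs no concentration input - and the fitted
midpoint is returned.  The fit runs from several starting midpoints
(landmark, half-amplitude crossing, span quartiles) keeping the best
chi-square, with Tm bounded to the measured ramp.  `refine=False` exposes
the raw landmark.

On the instrument's 5-90 degC, 1 degC ramp at the default CD noise the
extractor's standard deviation is ~0.2 degC for a mid-ramp transition and
~0.9 degC for a midpoint near 81 degC, where the unfolded baseline is
truncated by the ramp end; melt analyses therefore use n = 6 replicate
curves (the replication level of the membrane quantitation experiments)
and report the mean.

## Dissociation-gated kinetics

The solution scheme is integrated as ODEs (LSODA, rtol 1e-8, atol 1e-12):

    d[AB]/dt = kon[A][B] - koff[AB]
    d[B]/dt  = koff[AB] - kon[A][B] - kp*ks*[B] + kdp*ps*[Bp]
    d[Bp]/dt = kp*ks*[B] - kdp*ps*[Bp]
    d[A]/dt  = koff[AB] - kon[A][B]

with `ks`/`ps` the kinase/phosphatase activity multipliers.  Only free B
is phosphorylated and only free B' dephosphorylated - the recognition site
is buried in the dimer.  Enzyme events (kinase or phosphatase addition)
set the multipliers at event times by integration restart.  Enzymes are
pseudo-first-order (1 mM ATP >> peptide; no Michaelis-Menten saturation).
Temperature is a parameter-set label (25/37 degC presets), not an
Arrhenius law.  An optional weakened partial complex of A with
phosphorylated B exists behind `enable_partial_complex` (off by default).
A-total and B-family totals are conserved to 1e-6 relative and checked on
every trajectory.

**Tether mode** fixes a membrane anchor density (the anchor is permanently
His-tag-attached); soluble cargo binds free anchor with `kon_t/koff_t`
(the same CC interaction in a membrane context) and is phosphorylated only
in solution.  The membrane cargo signal is proportional to the
anchor-cargo complex; the anchor signal is constant.

**Avidity mode** gives every species a membrane state: monomers and the
dimer attach at `k1on` and monomers detach at `k1off`, while the dimer -
held by two MTSs - detaches at `k1off/avidity_factor`.  Dimerization is
allowed in both compartments; the on-membrane association rate `kon_mem`
defaults to the bulk `kon` but the avidity preset raises it to 1e4
uM^-1 min^-1 to represent the 2D concentration enhancement of
membrane-confined partners (without it, on-membrane dissociation destroys
the retained dimer and no avidity enrichment survives).  Phosphorylation
is routed through the solution pool by default;
`allow_membrane_phospho=True` additionally processes membrane-bound
monomeric B (released as solution B').

**Effective rates** are measured exactly as on real data: simulate, map to
the observable, fit the single-exponential rise.  The complexed
trajectories are not single exponentials (free partner accumulates and
progressively buffers the monomer pool), so the fitted rate depends on the
observation window; each preset therefore fixes its window to five
lifetimes of its published rate (`presets.OBSERVATION_WINDOW_MIN`), which
is part of the experiment definition.

**Observable maps**: CD interpolates MRE222 between folded/unfolded
endpoints by AB(t); HPLC counts B + AB as substrate area and B' as product
area, because reversed-phase column conditions denature the complex
(documented assumption); SLB channels are linear combinations of membrane
species (peak) and solution species (bulk background).

## Calibration of the presets

No kon/koff/Kd is published for any variant.  With the free-peptide rate
fixed at kp = 0.20 min^-1 (the published product-formation rate) and
koff = 10 min^-1 (fast exchange), `scripts/calibrate_presets.py` solved
each preset's dissociation constant - and, in avidity mode, the
fusion-protein kp - so that the *simulated experiment's fitted rate*
equals the corresponding published mean rate over that experiment's
window:

| preset | calibrated value | reproduces |
| --- | --- | --- |
| `hplc_AS_25C` | Kd = 0.94 uM | 8.0e-3 min^-1 (HPLC product, 50 uM) |
| `cd_AS_25C` | Kd = 1.24 uM | 9e-3 min^-1 (CD, 25 C) |
| `cd_AS_37C` | Kd = 33.0 uM | 8e-2 min^-1 (CD, 37 C) |
| `hplc_AN4_25C` | Kd = 0.45 nM (chosen) | 2-3 orders below the free rate |
| `tether_slb` | Kd_t = 1.05 uM | 0.07 min^-1 membrane release |
| `avidity_slb` | kp = 0.98 min^-1 (alpha = 30 fixed) | 0.10 min^-1 release, both channels |

These are calibrations, not measurements; the CD and HPLC values differ
because the two observables (dimer vs product) weight the non-exponential
trajectory differently.  In avidity mode the release rate is limited by
solution-phase processing rather than dimer detachment, which is why the
calibration dial is kp there.  The kinase-titration preset
(`partial_limiting_25C`) keeps the Ser-Ser' Kd but slows the exchange
(koff ~ 0.03 min^-1) so monomer rebinding competes with phosphorylation:
tripling the kinase then raises the observed rate ~2-fold rather than
3-fold, the signature of partial dissociation limitation.

## Imaging quantitation

The z-analyzer logic: each z-slice is collapsed to its (y, x)-mean
intensity; the profile maximum marks the membrane plane; the per-time peak
value gives the membrane-bound kinetic trace.  Peak areas integrate
(profile - baseline) by the trapezoid rule over a window of +/-3 slices
around the maximum, with the baseline a straight line through the medians
of 3 flanking slices per side - an automated, configurable stand-in for
manual bulk-solution subtraction.  Negative areas are reported, not
clipped.  Colocalization compares profile argmax positions with a default
tolerance of one slice.  The single-max-slice peak definition is a
documented choice (no sub-slice fitting).

## Synthetic data generator

Generators produce every input the pipeline consumes, from the forward
models, with explicit seeds (fixed seed => byte-identical output) and the
noiseless ground truth attached:

* **HPLC areas** - substrate/product trajectories, multiplicative noise,
  default CV 5%;
* **CD kinetics/melts** - MRE222 traces, additive Gaussian noise, default
  2% of dynamic range; melts on the 5-90 degC, 1 degC instrument ramp;
* **SLB stacks** - per channel and time, profile(z) = membrane(t) *
  Gaussian(z; z0, sigma_z) + bulk(t) expanded to (y, x) pixels with
  Poisson-approximated counting noise; defaults: 40 slices at 0.25 um,
  sigma_z = 0.5 um (confocal axial response; no full PSF), 16 x 16 pixels,
  coincident peaks across channels, constant lipid channel.

Not emulated: photobleaching, stage drift, FRET between the fusion
fluorophores, chromatogram peak shapes, enzyme saturation, pipetting and
dilution artifacts of reagent additions, and - important when reading the
t statistics - the biological replicate-to-replicate variability of real
SLB preparations: synthetic replicates differ only by noise realization,
so comparison statistics are far larger than experimental ones.  Passing
recovery tests therefore demonstrates the pipeline's correctness and
self-consistency, not instrument-level realism.

## Numerical choices

* ODEs: LSODA, rtol 1e-8, atol 1e-12; events by integration restart at the
  event time; conservation recorded on every trajectory.
* Exponential fits: initial guesses y0 = first point, y_inf = last point,
  k = 1/(time to half-range); k bounded to [0, 1e3 min^-1]; a fitted rate
  that resolves no decay over the window (k * span < 1e-6) or sits at the
  bound is flagged.
* Rank ties in partner ranking break alphabetically.
* Gillespie cross-checks (tests) use copy-number scale omega = 50/uM and
  compare ensemble means within 4 SEM.
* Seeds: every generator takes an explicit integer seed; derived seeds
  stay below 2^31.

## Known limitations

* Membrane compartments are a well-mixed proxy (surface quantities in
  uM-equivalents); there is no spatial geometry, diffusion, or
  reaction-diffusion patterning.
* The bundled sequences are reconstructions; absolute fusion masses are
  illustrative, and any comparison against externally printed construct
  masses will reflect the stand-in composition.
* The avidity enrichment magnitude trades off against the release rate
  under solution-routed processing; strong (>10x) enrichment together with
  fast release requires on-membrane phosphorylation (available via flag,
  off by default).
* Tm extraction near the end of the temperature ramp is noticeably noisier
  than mid-ramp; the replicate-averaging protocol above is the mitigation.
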