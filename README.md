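# circlock

A kinetic model of the mammalian circadian clock built from two
interlocked transcriptional feedback loops, packaged as a simulator with
the full battery of in-silico perturbation experiments and the
rhythm-analysis procedures used to score them.

## Who this is for

Chronobiologists and systems biologists who want to ask quantitative
questions of the core clock network — *how does Per transcript stability
set the period? what does the ROR/Bmal/REV-ERB loop contribute beyond
robustness? which gene dosages break rhythmicity?* — without wiring up
the ODEs themselves, plus a matching analysis pipeline for
bioluminescence-reporter recordings.

## The model

Nineteen coupled ODEs describe five gene entities (*Per*, *Cry*,
*Rev-Erb*, *Ror*, *Bmal* — gene families, not paralogs) through
transcription, translation, PER phosphorylation, complex formation,
nuclear transport and linear degradation, with 71 rate constants:

* **PC loop** — CLOCK/BMAL activates *Per* and *Cry*; PER and CRY form
  cytoplasmic complexes (with PER in hypo- and hyper-phosphorylated
  forms) that shuttle into the nucleus, where the pooled PER/CRY
  species inhibits all CLOCK/BMAL-driven transcription:

  $$v_g = V_g\,\frac{1 + f_g\,(x_1/k_{a,g})^{b_g}}{1 + (x_1/k_{a,g})^{b_g}}
  \cdot \frac{1}{1 + (\mathit{PC}/k_{i,g})^{c_g}}$$

  with $x_1$ = CLOCK/BMAL and $\mathit{PC}$ = PER/CRY\_N + PER\*/CRY\_N.

* **RBR loop** — nuclear REV-ERB and ROR compete for the RORE element
  of the *Bmal* promoter (activation in the numerator, repression in
  the denominator):

  $$v_{Bmal} = V_5\,\frac{1 + f_5\,(x_6/k_{a5})^{b_5}}
  {1 + (x_6/k_{a5})^{b_5} + (x_5/k_{i5})^{c_5}}$$

  REV-ERB additionally represses *Cry*, coupling the loops; nuclear
  BMAL binds constant CLOCK reversibly to regenerate the activator.

All remaining kinetics are mass action with linear decay. Concentrations
are in normalized arbitrary units (components oscillate around a
baseline of ~1). The shipped parameter set is calibrated so that the
wild-type limit cycle has a 23.5 h period, documented cycle means
(PER/CRY pool 1.71, CLOCK/BMAL 1.7, REV-ERB\_N 2.4, ROR\_N 5.8), a
25.1 h RBR-only oscillator, a damped 20.7 h PC-only oscillator, and
much of the documented knockout/RNAi phenotype pattern;
`docs/methods.md` states exactly which behaviours the calibration does
and does not reproduce.

## Worked example

```python
import circlock as cl

model = cl.build_default_model()        # 19 species, 71 parameters
traj  = cl.integrate(model)             # 40 days, last 20 analysed

print(round(cl.estimate_period(traj, "Bmal"), 2))     # 23.46
print(round(cl.mean_level(traj, "percry_pool"), 2))   # 1.71

# decouple the RBR loop: constitutive PER/CRY pool at its mean
rbr = cl.integrate(model, perturbations=[
    cl.clamp_at_mean(model, "percry_pool", traj)])
print(round(cl.estimate_period(rbr, "Bmal"), 1))      # 25.2

# a constitutive repressor at its mean level stops the whole network
wt = cl.summarize(traj, "Bmal")
clamped = cl.integrate(model, perturbations=[
    cl.clamp_at_mean(model, "REV-ERB_N", traj)])
s = cl.summarize(clamped, "Bmal", wt_relative_amplitude=wt.relative_amplitude)
print(s.oscillation_class)                            # arrhythmic
```

The printed numbers are the wild-type period (h), the mean nuclear
PER/CRY pool (normalized units), the slower period of the isolated
ROR/Bmal/REV-ERB oscillator, and the loss of rhythmicity when nuclear
REV-ERB is frozen at its mean (rhythmic repression drives *Bmal*).

Screens are one call each (`circlock.experiments`): `knockout_scan`,
`sirna_scan`, `transcription_gradient`, `degradation_scan`,
`decouple_rbr`/`decouple_pc`, `pc_robustness`, `rore_competition`,
`rainbow_scan`, `overexpression`, `fasps_scenarios`, `table1_replica`.
The same drivers are exposed on the command line:

```sh
circlock simulate --t-end 960 --discard 480 --scale dy1=1.5 --out traj.csv
circlock knockout --out ko.csv
circlock table1 --out table1.csv
circlock lumi fit --input plate.csv --control GFP --out report.csv
```

`circlock.lumi` processes reporter plate recordings (7 days, ~0.5 h
sampling): divide by a 24 h running average, fit a damped cosine
(multi-start least squares over 16–32 h), smooth 4 h for display, and
express conditions as fold change against controls. Seeded synthetic
fixtures — optionally driven by simulated Bmal trajectories — make the
pipeline testable offline.

The model exports to SBML L3V2 (`circlock.sbml.export_sbml`), and
`circlock export-sbml --out clock.xml` writes the document.

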