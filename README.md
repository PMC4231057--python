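# bbbassay

Analysis toolkit for quantifying radiation-induced blood-brain-barrier (BBB)
damage from standard wet-lab assays, aimed at barrier-biology and
radiobiology labs running transwell co-culture models and rodent
extravasation experiments. It implements the full measurement chain for:

- **transwell permeability**: per-interval cleared volumes, the
  permeability-surface product, cell-free filter correction, and the
  endothelial permeability coefficient Pe;
- **TEER**: area normalization and blank-filter subtraction of raw
  resistance readings;
- **Evans-blue extravasation in vivo**: linear plate calibration and ng dye
  per mg tissue, with bootstrap fold-changes versus sham;
- **count-based cellular endpoints**: endothelial-progenitor colony rates,
  SA-β-gal senescence fractions with exact binomial intervals, cell
  densities, and threshold-based immunofluorescence intensity;
- **group statistics**: one- and two-way fixed-effects ANOVA with Bonferroni
  dose-vs-sham post-tests;
- a seeded **forward simulator** of every assay, so each estimator can be
  validated end-to-end against known ground truth.

## The model

A transwell insert separates a luminal (donor, volume $V_d$ = 70 µl) from an
abluminal (receiver, $V_r$ = 530 µl) compartment across an endothelial
monolayer on a filter of area $A$ = 0.33 cm². Tracer exchange follows the
conservative two-compartment system

$$\frac{dC_r}{dt} = \frac{PS}{V_r}(C_d - C_r), \qquad
  \frac{dC_d}{dt} = -\frac{PS}{V_d}(C_d - C_r),$$

whose exact solution the simulator uses interval-by-interval (the insert
moves to a fresh receiver well at 20, 40 and 60 min; the receiver resets,
the donor carries over). The analysis inverts the protocol: the cleared
volume per sample is $C_a V_a / C_l$, its cumulative sum regressed on time
gives the total permeability-surface product $PS_t$ (µl/min), the bare
filter is removed in series,

$$\frac{1}{PS_e} = \frac{1}{PS_t} - \frac{1}{PS_f},$$

and $P_e = PS_e / A$ is reported in $10^{-6}$ cm/s. TEER is
$R_\text{raw} \cdot A - 70\ \Omega\,\text{cm}^2$ (the empty coated insert's
resistance). Tissue Evans blue is read off an inverted 7-point linear
standard curve and scaled by extract volume over tissue mass.

## Worked example

`examples/01_transwell_permeability.py` simulates 48 sham inserts per tracer
at 10% plate-reader noise (true Pe 0.21 and 0.043 ×10⁻⁶ cm/s) and runs the
full estimation chain:

```
  eb_albumin: recovered Pe = 0.0427 ± 0.0024 x10^-6 cm/s  (true 0.043, n=48)
 fluorescein: recovered Pe = 0.2068 ± 0.0103 x10^-6 cm/s  (true 0.21, n=48)
```

The mean recovered coefficients sit within ~2% of the simulator's ground
truth; the spread is the concentration noise propagated through the
clearance regression. The other examples cover TEER normalization
(`02`, recovering a 30% dose effect), in-vivo fold-changes (`03`, recovering
a two-fold leakage increase with bootstrap intervals), the count/image
endpoints (`04`), and the dose × time ANOVA with Bonferroni stars (`05`).

## Command-line pipeline

Each stage reads/writes plain CSV with a provenance JSON beside it:

```
bbbassay --seed 7 --out runs/demo simulate
bbbassay --out runs/demo permeability
bbbassay --out runs/demo evansblue
bbbassay --out runs/demo assays
bbbassay --out runs/demo stats
bbbassay --out runs/demo report
```

Identical config + seed yields byte-identical tables. A YAML `--config` can
override any design constant (volumes, area, sampling times, tracer doses,
blank TEER), the simulator's true parameters and effect structure, and the
statistics options.

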