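# Methods

## Transport model and the interval-transfer protocol

The transwell assay is modeled as conservative exchange between a luminal
(donor) and abluminal (receiver) compartment through a single lumped
conductance, the permeability-surface product PS (µl/min):

    dC_r/dt = (PS/V_r)(C_d − C_r),   dC_d/dt = −(PS/V_d)(C_d − C_r).

The concentration difference decays as exp(−PS(1/V_d + 1/V_r)·t) around the
equilibrium set by total tracer mass; `two_compartment_solution` evaluates
this closed form and is checked against an independent fixed-step RK4
integrator to ≤1e-6 relative error in the test suite.

The protocol moves the insert to a fresh receiver well at each sampling time
(20, 40, 60 min). The simulator therefore solves the system per interval
with the receiver reset to zero while the donor concentration carries over.
Donor depletion is modeled explicitly rather than assuming a sink: the sink
assumption is excellent for tight monolayers (donor loses <0.5% of tracer
over the hour) but fails for cell-free coated filters, whose conductance is
two orders of magnitude higher.

For a cell-bearing insert the simulated conductance is the series
combination of the endothelial layer and the filter, PS = Pe·A per barrier
and 1/PS_t = 1/PS_e + 1/PS_f; cell-free inserts carry PS_f alone.

## Estimation chain

Per insert: cleared volume per interval C_a·V_a/C_l; cumulative sum across
intervals; OLS of cumulative clearance on time with the origin (0, 0)
prepended and a free intercept (only the slope, PS_t, is used — the free
intercept absorbs any lag without forcing the line through zero); series
correction 1/PS_e = 1/PS_t − 1/PS_f with PS_f the mean slope over the
tracer's cell-free inserts on the plate; Pe = PS_e/A converted from µl/min
to the 10⁻⁶ cm/s scale (×10⁻³/60).

Two deliberate conventions:

- **C_l is the nominal initial donor concentration** (10 µg/ml fluorescein,
  165 µg/ml Evans blue–albumin), not an end-of-assay luminal measurement.
  For monolayers the resulting bias is <1%. For cell-free inserts the same
  convention understates PS_f by ~5–15% (donor depletion is real there), but
  because PS_e ≪ PS_f the error this injects into Pe is of order
  (PS_e/PS_f)·δ — under 0.3% at the defaults — and the end-to-end noise-free
  inversion test confirms recovery within 1%.
- **Cumulative clearance**: receiver resets at transfers make per-interval
  cleared volumes roughly equal; summing them before the regression is what
  makes the slope the conductance of the whole hour.

Inserts whose apparent PS_t reaches or exceeds PS_f violate the series model
(a monolayer cannot out-conduct its bare filter); such rows are flagged,
excluded from Pe with a logged warning, and left visible in the output.

TEER is raw ohms × area minus the 70 Ω·cm² blank, clipped at zero with a
flag when a leaky monolayer reads below the blank.

## Synthetic-data generator

The generator's defaults are the study conditions: geometry 70/530 µl and
0.33 cm², samples at 20/40/60 min, doses 0/0.1/2/10 Gy, in vitro days
1/2/3/5, in vivo timepoints 1 day and 1/4/26 weeks, sham Pe 0.21 and
0.043 ×10⁻⁶ cm/s, sham TEER 382.6 Ω·cm² with 80.4 Ω·cm² between-insert SD,
in vivo n=12 per group at 20% CV, 19 senescence coverslips of 400–500
counted cells.

Values the source experiments do not pin down were fixed once as plausible
bench numbers and are all overridable: cell-free filter Pe 20 (fluorescein)
and 5 (albumin) ×10⁻⁶ cm/s; sham tissue Evans blue 15 ng/mg (only relative
changes are meaningful); plate calibration slope 2 units per ng/ml with
intercept 50; tissue masses 200/60 mg (adult cerebrum/cerebellum, ×0.6 for
infants); CEP baseline 2 CFU per 10⁵ PBMC; cell density 800 /mm² with
0.1 mm² fields.

The effect structure mirrors the study's qualitative findings: two-fold
in-vivo leakage at 1 week in adults (all doses), the same effect delayed to
week 4 in infants, full recovery by 26 weeks; Pe elevated from day 2 at
2/10 Gy (multipliers 2.0–2.5 on day 2, decaying by day 5) with a delayed
fluorescein-only 1.5× effect at 0.1 Gy on days 3–5; a 0.7× TEER multiplier
at 10 Gy day 2; senescence fractions ×1.3/×1.4 at 2/10 Gy; progenitor
colonies halved one day post-irradiation at 0.1/2 Gy.

Noise model: mean-one multiplicative lognormal (default CV 10%) on measured
concentrations — plate-reader noise scales with signal — and additive
Gaussian on raw resistance readings with SD equal to the noise CV times the
layer's own resistance (TEER/area), so a 10% noise setting yields a 10% CV
on recovered TEER; biological spread between inserts is a separate normal
component. Counts are Poisson (colonies, cells per field) or binomial
(senescence positives). Every generator requires an explicit seed and is
bit-reproducible.

What the simulator does **not** emulate: pipetting-volume errors and
evaporation, temperature drift within the hour, non-linear plate saturation
at high dye concentrations, spatial heterogeneity of monolayers, correlated
errors between tracers measured on the same insert, and animal attrition.
Passing recovery tests therefore demonstrates that the estimators invert the
idealized assay correctly at realistic noise levels — not that they are
robust to every failure mode of real plates.

## Statistics

Two-way fixed-effects ANOVA with interaction uses Type III sums of squares
under sum-to-zero contrasts (via statsmodels), matching the convention of
the GUI statistics packages common in this field; on balanced tables it
coincides with the textbook sequential decomposition (verified to 1e-10).
One-way ANOVA is the standard F test. Post-tests against sham use t
statistics with the pooled error variance of the full interaction model —
equal to the within-cell residual mean square, which is how
`bonferroni_vs_sham` computes it when no ANOVA result is supplied — with
Bonferroni family size m = (non-sham doses) × (timepoints) by default (every
starred comparison of a dose-time figure), or per-timepoint as an option.
Adjusted p is min(1, m·p); stars follow p<0.05/0.01/0.001. A 2000-replicate
null simulation in the test suite confirms family-wise type-I error at or
below the nominal 5%.

Fold-changes versus sham are ratios of group means with a seeded
nonparametric bootstrap (2000 resamples, percentile 95% interval). The
senescence fraction carries an exact Clopper–Pearson interval computed from
beta quantiles.

Degenerate inputs: constant-response ANOVA returns F=0, p=1 exactly (rather
than floating-point noise ratios); calibration readings below the curve's
intercept clip to zero concentration with a flag, since plate noise makes
small negatives routine; TEER below the blank clips to zero with a flag.

## Image intensity

"Stained area" is segmented by Otsu's threshold (deterministic; a manual
threshold override is provided). Background is defined as the mean of the
sub-threshold, non-expressing pixels and subtracted from every pixel
(floored at zero) before averaging the above-threshold pixels. The measure
is exactly invariant to additive offsets and scales linearly with detector
gain on two-level images.

## Problem sizes and replication in the recovery checks

The recovery checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` run the exact study designs: 48 inserts per tracer
at 10% CV for Pe recovery; 48 TEER readings per plate from the control
distribution; sham vs 10 Gy day-2 TEER groups of n=16 at 10% noise; adult
1-week in-vivo groups of n=12 at 20% CV; 19 senescence coverslips per group.
Quantities that are stochastic at those group sizes (TEER mean and percent
decrease, senescence relative increase — single-experiment sampling SDs of
roughly 2.5–3.5 points) are reported as the mean over 4–8 independent
replicate simulated experiments spawned from the given seed, so the reported
number is the estimator's central value at the prescribed design rather than
one draw; group sizes, noise levels and effect sizes are never altered.

## Known limitations

- The series correction assumes the monolayer and filter behave as
  independent conductances; unstirred water layers are absorbed into PS_f.
- PS_f pooling is per plate per tracer; plates with a drifting filter lot
  need the config override.
- Type III ANOVA requires every dose × time cell to be non-empty; designs
  with structurally missing cells need a cell-means reformulation.
- The bootstrap interval for fold-changes is percentile-based and can be
  short at n ≤ 5 per group.
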