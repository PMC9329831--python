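# Methods

This note documents the models, rules and numerical choices the package
implements, and what its synthetic cohorts can and cannot demonstrate.

## Estimating equations

All equations operate in mg/dL.  Conversions use the standard clinical
factors 0.02586 (cholesterol mg/dL → mmol/L), 0.01129 (triglycerides) and
0.01 (apoB mg/dL → g/L); conversion and its inverse are exact reciprocals.

* **Friedewald**: `VLDL-C = TG/5`, i.e. a constant VLDL-C/TG ratio of 0.2.
  Implemented mainly as the baseline the other estimators are compared
  against: as a ratio score it carries no discriminating information.
* **Sampson-NIH equation 1**: `TG/8.56 + (TG·non-HDL-C)/2140 − TG²/16100`,
  with no intercept.  These coefficients are not derived here; they ship in
  a frozen `SampsonConstants` record carrying its citation, and
  `sampson_vldlc` refuses to run with an uncited or absent record rather
  than silently defaulting.
* **Enhanced (apoB-augmented) equation**: the same lipid terms plus HDL-C,
  apoB and an apoB×TG interaction, with denominators 3.81, −8.93, 7.73,
  2050, −13300, −2.49, −3550 and intercept +7.46.  The estimate is strictly
  decreasing in apoB at fixed lipids.  Outputs are returned unclamped —
  negative estimates are genuine failure modes the evaluation layer must be
  able to observe — and a missing apoB raises an error instead of falling
  back to the apoB-free equation.

## Diagnostic rules

The reference (beta-quantification) definition of HLP3 is
`VLDL-C/TG ≥ 0.3 and 150 ≤ TG ≤ 1000 mg/dL`.  Both comparisons are
inclusive by default: recorded HLP3 cases can sit exactly at ratio 0.30,
which an exclusive reading would misclassify.  Both inclusivity choices are
switches on `RunConfig` for sensitivity analyses.

The estimated-ratio screens apply the same TG window; a record outside the
window is a *negative*, not an unevaluable call, so that screening
sensitivity and specificity are computed over the same denominators as the
reference rule.  `TG = 0` (ratio undefined) and missing apoB (enhanced
ratio not computable) produce `not_evaluable` calls; the confusion-matrix
layer excludes those by default and reports their count, with a strict mode
that counts them as negatives.

The dual apoB ratio rule is evaluated in SI units internally
(TC/apoB ≥ 6.2 and TG/apoB ≤ 10 with lipids in mmol/L, apoB in g/L), so it
is invariant to the caller's unit system once the I/O layer has normalised
to mg/dL.

Cohort exclusion filters drop records with detectable lipoprotein-X (an
input flag; electrophoresis itself is not modelled), TG > 3,000 mg/dL or
TC > 1,500 mg/dL.  A record failing several rules is counted under each
flag but removed once; the filter is idempotent.

## Equation derivation

`fit_vldlc_equation` performs ordinary least squares on an explicit term
basis.  The published equation retains every candidate term, so full-basis
OLS is the reference path; backward stepwise elimination (p-to-remove 0.05)
is available behind a flag.  Term columns span five orders of magnitude
(TG² reaches ~10⁷), so columns are scaled to unit norm for the solve and
coefficients back-transformed; rank deficiency is detected and reported
with the offending terms.  Noise-free coefficient recovery to 1e−8 relative
is the module's core oracle test.

Accuracy diagnostics (MAD, RMSE, R², slope, intercept) regress the
*reference on the estimate* by default — the orientation used when the
measured value is plotted against the calculated one — and the orientation
is recorded and configurable.

The train/validation split is simple random sampling at fraction 0.5
(unstratified), reproducible under a seed.  HLP3-subset fits re-use the
same machinery restricted to reference-positive records; the result is
flagged `hlp3_specific` and refused by the screening interface, because an
equation fitted on the enriched subset overestimates VLDL-C in the general
population and must only be used to monitor already-diagnosed patients.

## Diagnostic-test evaluation

ROC thresholds are the midpoints between adjacent distinct scores plus
∓∞ sentinels; a call is positive when `score ≥ threshold` (the inclusive
convention, exposed in config).  AUC is the Mann–Whitney statistic with
ties counted ½, computed from average ranks; sensitivity and specificity
are plain count ratios so that tied Youden sums compare exactly.  The
operating cut-point maximises sensitivity + specificity; ties resolve to
the *higher* threshold (higher specificity), a deliberate choice for a
condition with ~0.5% prevalence where false positives dominate cost.  A
degenerate curve (all scores tied) returns the +∞ sentinel with a warning.
Normalized MCC is `(MCC+1)/2`; MCC with an empty margin is defined as 0.
Group comparisons use means, linear-interpolation quartiles, and the
unequal-variance (Welch) t-test.

## Synthetic cohorts

The generator emulates a dyslipidemic referral population with a rare
(default 0.5%) HLP3 minority.  Analyte marginals are truncated lognormals
calibrated to mean/IQR/min/max summaries; quartile matching is exact and
closed-form (σ from the log-IQR, μ the log-median), while the implied mean
is *reported, not forced* — three targets over-determine a two-parameter
law (e.g. the majority-group TG summary implies a mean of ~143 mg/dL
against a target of 164).

Per record, group membership is Bernoulli at the prevalence; the VLDL
fractions close the compositional identities exactly (VLDL-TG and LDL-C
are solved from the sums and the whole record is redrawn until both are
positive, capped at 100 rounds before an infeasibility error).  Every HLP3
record is reference-positive by construction (enrichment ratio drawn in
(0.30, 0.69), TG drawn inside the window) and every non-HLP3 record is
reference-negative (in-window records keep ratio < 0.3).

Three dependence features of real panels are built in, with defaults chosen
to make the simulated population behave like the one the equations were
designed for:

* **TG–TC copula 0.45** — mixed dyslipidemia raises both lipids; without
  it the simulation is dominated by low-TG/high-cholesterol panels that do
  not occur in practice, whose 1/TG equation terms produce spuriously
  extreme ratio scores.
* **apoB–non-HDL-C copula 0.95** — apoB is the particle count behind
  non-HDL cholesterol and tracks it tightly in clinical data.  The residual
  of apoB at fixed non-HDL-C is the "particle count at fixed cholesterol"
  axis that only an apoB-aware estimator can see.
* **Conditional-mean anchoring of the majority-group ratio** — the true
  enrichment ratio of a non-HLP3 record is drawn around the panel-implied
  remnant enrichment (the apoB-aware estimate divided by TG) with an
  independent residual of SD 0.03.  This encodes the defining property of
  the source population — that the apoB-augmented equation is approximately
  the conditional mean of measured VLDL-C given the panel — while the
  induced marginal stays inside the summary band (mean ≈ 0.168,
  IQR ≈ 0.11–0.21 at cohort scale).

Age (uniform 18–90) and sex (50/50) are independent of the lipids.
Cohorts are byte-for-byte reproducible under the spec seed.

**What passing tests show, and do not show.**  Because the generator
anchors the majority-group enrichment on the apoB-aware prediction, the
directional benchmarks (enhanced > standard > Friedewald in AUC, and the
reverse ordering in MAD against a noisy reference) demonstrate *internal
consistency* — the evaluation machinery ranks estimators correctly on a
population with the dependence structure the enhanced equation was built
for — not independent clinical validation.  Real referral data differ in
ways the generator does not model: analyte correlations beyond the three
encoded above, age/sex effects on lipids, assay-specific bias, secondary
dyslipidemias, and the true joint tail behaviour.  Feasibility rejection
also shifts the TG-family means upward of their calibrated marginals
(analytes untouched by the closure constraint — TC, HDL-C, apoB — converge
to the calibrated means within 2%).

## Problem sizes and tolerances

Default benchmark sizes are a 20,000-record cohort at prevalence 0.005
(~100 positives), 1,000 noise-free panels for coefficient recovery, and
100 random instances (n ≤ 500) for ROC oracle equivalence — sizes at which
every check is decisive yet the full suite runs in seconds.  Key
tolerances: equation-vs-oracle agreement 1e−9 mg/dL; noise-free recovery
0.1% relative (it is exact up to conditioning); noisy recovery (σ = 5
mg/dL at n = 10,000) 5% on slopes and 10% on the small intercept,
calibrated by Monte Carlo; unit round trips 1e−12 relative.  The
measurement noise applied to the simulated reference in accuracy
benchmarks is Gaussian with σ = 5 mg/dL, a realistic scale for enzymatic
cholesterol assays.
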