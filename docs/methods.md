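# Methods

## The model

`momscreen` implements the statistical core of first-trimester serum
screening for preeclampsia. The screening problem: given a marker panel
measured at 8+0–13+6 weeks of gestation plus maternal characteristics,
estimate each pregnancy's risk of early-onset (delivery < 34 weeks, EO-PE)
or late-onset (≥ 34 weeks, LO-PE) preeclampsia, and summarise a model by the
fraction of affected pregnancies it flags (detection rate, DR) when the risk
cutoff is set so that 10% of unaffected pregnancies screen positive
(false-positive rate, FPR).

Marker concentrations depend strongly on gestational age at sampling, so all
modelling happens on the multiple-of-the-median (MoM) scale. The package
assumes — in both its normalization machinery and its generator — the
standard serum-screening marker model: within unaffected pregnancies at
gestational age *g* (days),

    x = m(g) · 10^ε,   ε ~ N(0, σ²),   log10 m(g) = a + b·g

i.e. log-Gaussian MoMs with median 1, and a case population shifted
multiplicatively by a MoM ratio (MoMR). Mean arterial pressure,
MAP = DBP + (SBP − DBP)/3, is treated throughout as one more marker on the
MoM scale.

## Pipeline stages and their conventions

**Detection filter.** An analyte must be detected in strictly more than 80%
of samples ("more than 80%" is read literally, so exactly 80% is dropped).
The fraction is pooled over all groups and splits by default; a
controls-only variant is available via `detection_fraction` on a subject
subset. Surviving below-LOD cells are imputed as half the lowest detected
value of that analyte — a compromise between substituting zero and
truncating at the LOD. Imputation is idempotent and never touches detected
values.

**Splitting.** 40/30/30 train/test/validation within each outcome group,
with round-half-up on the train and test sizes and validation as the
remainder. This is the only simple rounding rule consistent with all nine
per-group counts of the reference design (500 → 200/150/150, 68 → 27/20/21,
99 → 40/30/29); the convention is inferred from those counts and documented
as such.

**Median curves.** Per marker, the median concentration and count n of each
completed gestational week (week w = days 7w..7w+6; the sampling window
spans weeks 8–13) among training-set controls are computed, and
log10(median) is regressed on the week midpoint in days by weighted least
squares with weights n. Regressing the log median guarantees positive
predicted medians over the whole window; requiring ≥ 2 represented weeks is
the minimal identifiability condition. Gestational age is fully handled
here and is deliberately *not* re-adjusted in the covariate step (avoiding a
double correction).

**Covariate adjustment.** For each marker, maternal weight (continuous),
smoking (binary) and ethnicity (categorical) are screened for association
with log10 MoM among training controls — regression t-test, two-sample
t-test and one-way ANOVA respectively — at two-sided p < 0.05 (the gate
level is a package choice; "significantly different" is not quantified in
standard practice). Flagged covariates are fitted jointly by least squares
and subtracted on the log10-MoM scale, centred at the training-control mean
so an average-covariate control is unchanged. This is equivalent to
dividing the MoM by its expected value given covariates, the usual
Cuckle–Wald correction. Constant covariates are skipped with a warning.

**Marker selection.** Per outcome, a two-sided Student's t-test (pooled
variance; Welch available as an option) on log10 MoMs between training cases
and training controls, Benjamini–Hochberg q-values computed across the full
tested panel of that outcome (amines, oxylipins and MAP as one family —
whether the original analysis pooled platforms is unknowable from the
printed tables, so the simplest family is used and reported), and a strict
q < 0.15 gate. BH is implemented directly (the step-up with monotonicity
enforcement) and cross-checked against `statsmodels.multipletests` in the
tests.

**Risk models.** Plain maximum-likelihood logistic fits (statsmodels
`Logit`, Newton, tolerance 1e-8, ≤ 100 iterations; no regularisation — the
term counts are tiny). The prior-risk model regresses outcome on
nulliparity, weight, hypertensive history and smoking within the training
set. A binary characteristic with an empty outcome-by-level cell in the
training set has an infinite MLE (quasi-separation) and is dropped with a
warning, recorded in the model metadata; with a 0.8% control prevalence of
hypertensive history this happens in a sizeable fraction of 200-control
training sets and is the standard pragmatic remedy. Candidate combined
models are the prior risk plus every subset of {MAP} ∪ selected markers
(MAP participates only when it passed the FDR gate). MAP enters on the MoM
scale and metabolites as log10 MoMs, matching the structure of published
prediction rules. The prior risk enters as its log-odds used as one fitted
covariate by default; an "offset" mode (coefficient fixed at 1) is provided
because printed screening rules often show only marker terms, leaving the
prior's incorporation ambiguous — neither mode is asserted as the original
study's.

**Evaluation.** The risk cutoff is the (1 − FPR) empirical quantile of the
control scores under the inverse-ECDF convention (the ⌈(1−FPR)·n⌉-th
control order statistic), with positivity by strict `>`; this is exactly
reproducible and is verified against an exhaustive threshold scan in the
tests. DR confidence intervals are Wilson score intervals (the CI method
of the reference tables is unstated; Wilson is a documented package
choice). AUC is the Mann–Whitney probability with ties counted 1/2. The
best model is the one with the highest test-set DR, ties broken toward
fewer terms — the parsimony rule that rejects a larger model offering no DR
gain. The chosen model is then evaluated once on the validation set, and
within the birthweight < 10th centile (SGA) and ≥ 10th centile (AGA) case
subgroups against all validation controls; an empty subgroup yields an
explicit empty marker, not a crash.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the measurement process. Defaults reproduce the reference study design:
500 controls, 68 EO-PE, 99 LO-PE; integer gestational ages uniform on days
56–97; a panel of 58 amines and 46 oxylipins plus MAP (105 variables), null
effects everywhere except taurine (MoMR 0.79, EO), asparagine (0.84, EO),
glycylglycine (0.72, LO) and MAP (1.10 EO / 1.07 LO). Maternal covariates
follow the published cohort table: weight means 65.5/70.0/67.5 kg (SD 10),
smoking 4.2/11.8/6.1%, nulliparity 46.6/80.9/72.7%, hypertensive history
0.8/5.9/10.1% for controls/EO/LO. Where the sources print no value the
defaults are typical serum-screening magnitudes, chosen once: log10 MoM SD
0.10 for amines, 0.15 for oxylipins, 0.04 for MAP; MAP median 85 mmHg with
pulse pressure N(40, 5) mmHg solving the MAP identity into SBP/DBP pairs;
delivery weeks and birthweight centiles drawn to match the group medians
(normal and Beta shapes respectively). Two oxylipins carry 25% below-LOD
censoring (so the detection filter has real work) and two amines 5% (so
imputation does); the LOD is the empirical `lod_quantile` point of the
control marginal, applied to all groups. Markers are independent by default
— the real correlation structure is unpublished — with an optional
correlation matrix applied on the log10-MoM scale via Cholesky.

What the generator does *not* emulate: chromatographic/MS noise, batch
effects and QC drift, assay-specific LOD mechanisms, marker–marker
correlations, case–control differences in gestational age at sampling, twin
pregnancies or the cohort's exclusion cascade. Passing tests therefore
demonstrate that the *statistics* are implemented correctly and are
well-calibrated under the assumed marker model — not that the pipeline
would achieve any particular detection rate on real sera.

## Numerical and degenerate-input choices

- Round-half-up (`floor(x + 0.5)`) for split sizes, never banker's rounding.
- Weighted least squares via `lstsq` on √n-scaled rows; weekly weights are
  scale-invariant (doubling all n leaves the fit unchanged).
- MoM computation refuses gestational ages outside days 56–97 and
  non-positive concentrations; an analyte with zero detected values cannot
  be imputed and raises.
- t-tests raise on groups of < 2 values or zero pooled variance.
- BH q-values are order-preserving and permutation-equivariant; p-values
  outside [0, 1] raise.
- Logistic fits raise a diagnostic `FitError` on rank-deficient designs,
  separation or non-convergence (except the documented quasi-separation
  drop in the prior model).
- `fpr = 1` places the cutoff below every control so DR = 1; `fpr = 0` is
  rejected (no finite empirical cutoff exists under strict `>`).
- Wilson bounds are clipped to [0, 1] against floating-point undershoot.

## Problem sizes used by the tests and acceptance script

Effect-size recovery runs use 5000 cases + 5000 controls per marker (median
curves fitted on the 2000 training controls), where the Monte-Carlo error of
a median MoM ratio is ≈ 0.003 — comfortably inside the ±0.02 check.
Printed-rule coefficient recovery refits on 200,000 simulated outcomes with
MAP-MoM ~ N(0, 0.04) and taurine log-MoM ~ N(0, 0.10); at that size the
sampling SD of the taurine coefficient is ≈ 0.08 (≈ 3% of its magnitude),
so single-seed recoveries of that one coefficient scatter at the edge of a
±3% band — the intercept and MAP coefficient are an order of magnitude
better determined. Null-FDR calibration uses 500 vectorised replicates of a
105-marker, 27-vs-200 design; the power and end-to-end comparisons use
20 and 100 study-scale replicates respectively over a reduced panel that
keeps the effect-carrying markers. The full default run
(667 subjects × 105 variables, both outcomes, all candidate subsets)
completes in about two seconds.

## Known limitations

- The generator's dispersions are assumptions; absolute DR levels on
  synthetic cohorts track those assumptions, which is why the package's
  own checks are calibration and recovery properties, not DR values.
- Median curves are straight lines in log10 concentration; no spline option.
- The prior-risk model is refit per cohort — published prior-risk
  coefficient sets are not reproduced.
- Single fixed split, as in the underlying design; no cross-validation.
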