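# Methods

## The procedure

`mirpanel` implements a three-phase circulating-biomarker workflow:
candidate markers are screened and panels selected on training-phase
samples only, then the fixed panels are evaluated on the independent
validation phase, and finally each panel's discrimination is compared to a
reference marker (CA 19-9). The statistical machinery, stage by stage:

**ΔCt normalization.** Measured expression is `x(s, m) = Ct_U6(s) −
Ct_m(s)`. The orientation (reference minus target) makes larger values
mean higher abundance; a linear SVM is sign-invariant, so this choice only
affects the interpretability of the weights and box plots. No fold-change
(`2^−ΔΔCt`) transform is applied: the pipeline stays on the additive ΔCt
scale throughout.

**z-scoring.** Each miRNA is standardized with mean and sample sd
(denominator n−1) estimated on a designated fit set. The default scope is
`train`: statistics come from the training-phase samples of the comparison
at hand and are applied unchanged to validation samples, so no
validation-phase information leaks into the model. A `pooled` scope is
available for replication of analyses that standardized globally.

**Screening.** Per-miRNA two-sample Student (pooled-variance) t-test;
selection is strictly `P < α` with α = 0.05 and no multiplicity
correction — the screen is a candidate-reduction step, not an inference.
Benjamini–Hochberg q-values are printed for transparency but never drive
selection. Welch's variant is available behind a flag. Degenerate
zero-variance markers get `P = 1` when the group means agree and `P = 0`
(with a warning) when they do not.

**Linear SVM.** The classifier is the standard C-soft-margin linear SVM
(default `C = 1`, the default of the solver family this method is built
on); the decision value is `f(x) = wᵀx + w₀` and a sample is called
positive iff `f(x) > 0`. The positive class is the cohort listed first in
a comparison (PC in "PC vs CP"). Fits go through libsvm's low-level
binding (the solver inside scikit-learn's `SVC`): wrapper selection
performs ~10⁵ fits per run and the estimator-level API spends most of its
time re-validating inputs. The binding's orientation convention is pinned
by a regression test against `SVC`, and the solver itself is checked
against an independent constrained-optimization oracle on small problems.
The solver tolerance defaults to libsvm's own 1e-3; much tighter
tolerances can cycle pathologically on degenerate one-dimensional
subproblems, and the decision values and metrics are insensitive at this
scale. Tests that need the exact optimum pass a tighter tolerance
explicitly.

**Balanced bootstrap hold-out validation.** Per replicate: (i) both
cohorts are downsampled without replacement to the size of the smaller
one (fresh draw every replicate — this maximizes data use and is why the
procedure is a bootstrap over splits rather than a single split); (ii) a
fixed hold-out (10 samples for validation-phase evaluation, 6 for
training-phase/inner-selection evaluation) is drawn at random, redrawing
up to 100 times if either side lacks a class; (iii) the SVM is trained on
the remainder and scored on the hold-out. Accuracy, sensitivity,
specificity and the Mann–Whitney rank AUC of the decision values are
averaged over replicates, and each metric's **SE is the across-replicate
standard deviation** — the bootstrap estimate of the metric's sampling SD,
not sd/√reps. (Published SEs of this design, e.g. 0.097 on an AUC of
0.891, are only consistent with the across-replicate SD reading, and the
Z comparison below treats SEs as sampling SDs.) Replicates whose hold-out
lacks a class still contribute accuracy but not the class-conditional
metrics. For the reference marker the raw CA 19-9 value is the decision
score (no training step); its classification threshold defaults to the
conventional 37 U/mL cutoff and affects only accuracy/sensitivity/
specificity, never the AUC.

**Sequential forward selection.** Greedy wrapper selection over the
screened candidates: at each step every remaining candidate is scored by
the balanced bootstrap (hold-out 6, 200 replicates by default,
configurable to 1000) under a per-step common seed, so all candidates of
a step see identical resampling; the best mean objective (accuracy by
default, AUC optional) wins. Ties within 1e-12 break by smaller
univariate screening P, then lexicographic name, making selection fully
deterministic. Because selection is greedy and step seeds do not depend
on the target size, the size-3 panel is always the prefix of the size-6
panel. No backward or floating steps.

**AUC comparison.** `Z = (AUC₁ − AUC₂)/√(SE₁² + SE₂²)` with one-sided
`P = 1 − Φ(|Z|)`; Z is reported signed. This is deliberately the
independent-SE normal test on bootstrap SEs, not DeLong's paired
covariance test: with SEs estimated by the balanced bootstrap the
independent-SE form is the internally consistent choice, and it is the
form whose published values this package's tests reproduce. A paired
DeLong test on shared samples would generally give larger |Z|; anyone
needing it can feed the exported decision values to a ROC package.
Report rounding: AUC/SE to 3 dp, Z to 2 dp, P to 1 dp.

## The synthetic cohort generator

The generator emulates the measurement model the analysis assumes, on the
Ct scale:

- `Ct(miR m) = ct_base_mean − δ_{m,cohort} + N(0, ct_base_sd)` — an
  abundance effect is a *downward* Ct shift (earlier amplification);
- `Ct(U6) ~ N(u6_mean, u6_sd)` independently per sample;
- `CA 19-9 = exp(N(ca199_log_mean_cohort, ca199_log_sd))`, log-normal and
  strictly positive.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| cohorts | PC 184, CP 72, OPN 84, HC 20 | matches the scale of a multicenter plasma study (~360 samples) |
| `train_fraction` | 0.3 | roughly a quarter-to-third training phase, enough CP training samples for balanced inner evaluation |
| `ct_base_mean`, `ct_base_sd` | 30, 0.8 cycles | typical plasma-miRNA Ct range and technical+biological spread |
| `u6_mean`, `u6_sd` | 24, 0.6 cycles | abundant reference gene, tighter than targets |
| informative δ (PC) | 1.1 / 1.0 / 0.9 and 0.75 / 0.70 / 0.65 | three moderate markers carry most signal; three weaker ones are univariately detectable but largely redundant, so panel growth plateaus after size 3 |
| `ca199_log_mean` | PC 4.50, CP 3.43, OPN 2.97, HC 2.80 (sd 1.0) | log-normal CA 19-9 with PC median ≈ 90 U/mL; the pairwise closed-form AUCs are 0.775 (PC/CP), 0.860 (PC/OPN), 0.626 (CP/OPN), the clinically expected ordering |

Two structural properties matter for testing:

1. **Unit normalized variance.** `ct_base_sd² + u6_sd² = 0.8² + 0.6² = 1`,
   so a single marker with shift δ separates two cohorts with AUC exactly
   `Φ(δ/√2)` — the closed-form oracle the calibration tests use.
2. **Shared reference noise.** Because every normalized marker contains
   the same U6 draw, any two markers are correlated (ρ = `u6_sd²` = 0.36
   at the defaults). This mirrors real ΔCt data and has a genuine
   consequence: a pure-noise marker can *improve* a panel by cancelling
   the common reference noise, so "the informative markers" and "the
   optimal panel" are not the same thing under correlated noise. The
   marker-recovery experiments therefore use a near-independent variant
   (`u6_sd = 0.1`, `ct_base_sd = √0.99`), where the planted markers are
   provably the optimal subset.

What the generator does **not** emulate: microarray/TLDA probe chemistry,
amplification-efficiency differences, plate or center batch effects,
non-Gaussian expression tails, missing values, or any correlation between
CA 19-9 and the miRNAs. Passing tests show the *procedure* is correct and
calibrated under its own assumptions; they say nothing about how large
real plasma-miRNA effects are.

## Scaled-down study sizes

The test suite and acceptance script keep every simulation at a size a
single CPU handles in minutes, as the package's own defaults: screening
calibration uses 1000 cohorts of 50/50 samples; marker recovery uses 50
cohorts of 60/60 with 200 inner bootstrap replicates; validation examples
use 1000 replicates. The null-accuracy check spreads its 1000 replicates
over 10 independent cohorts of 200/200: a single finite null cohort has
chance structure of order √(k/n) that the classifier legitimately picks
up, so averaging over cohorts — not just over replicates — is what tests
the procedure's calibration.

## Numerical and design choices

- **Determinism.** Every stochastic step consumes a `numpy` Generator
  seeded from the run configuration; per-step selection seeds are derived
  arithmetically, and identical configs reproduce every numeric output
  byte for byte (the config echo records all seeds).
- **Degenerate inputs.** Zero-variance markers fail z-scoring with the
  marker named; one-class inputs fail training, AUC and balancing with
  the class named; bootstrap splits that cannot contain both classes in
  training are redrawn; `compare_auc` with two zero SEs returns Z = 0 on
  equal AUCs and flags ±∞ otherwise.
- **File formats.** All inputs and outputs are delimited text; Ct tables
  round-trip bit-exactly (cells are parsed with Python float semantics
  because fast CSV float paths can be off by one ulp). Missing Ct cells
  are rejected by default or kept as NaN behind an explicit flag.
- **Discovery order.** Panel selection always operates on the *screened*
  candidate set. This matters: wrapper selection alone, at desk-scale n,
  frequently swaps a weak planted marker for a cohort-idiosyncratic noise
  marker that genuinely scores better in-cohort; the univariate screen
  removes exactly those markers because their panel value comes from
  correlation structure, not marginal signal.

## Known limitations

- The multivariate discovery-phase screen of the original three-phase
  design (hundreds of microarray probes down to tens of candidates) is
  not reconstructed; the pipeline starts from a candidate Ct table.
- The independent-SE Z test understates significance relative to a paired
  DeLong test when both scores are computed on the same samples.
- Wrapper forward selection optimizes in-cohort resampled performance; at
  small n this is not the same as recovering the generatively informative
  markers (see the discovery-order note above), and no claim is made that
  selected panels are globally optimal subsets.
- CA 19-9 sensitivity/specificity depend on the configurable 37 U/mL
  cutoff; only its AUC is threshold-free.
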