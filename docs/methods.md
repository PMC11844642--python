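# Methods

## The model

qPCR reports, per sample and gene, a cycle threshold CT — the cycle at
which fluorescence crosses a detection line. With per-cycle amplification
efficiency e ∈ (0, 1], product grows by (1+e) per cycle, so CT is a
base-(1+e) logarithm of starting abundance, inverted (more transcript →
lower CT). At e = 1 it is exactly −log2(abundance) up to an assay
constant.

The package's central analysis is an ANCOVA fit by ordinary least
squares:

    CT_target,i = β0 + β_trt · treated_i + Σ_f β_f · dummy_f,i
                  + k · CT_reference,i + ε_i,     ε_i ~ N(0, σ²)

Treatment and nuisance factors (typically the donor) are
treatment-contrast dummy coded; the reference gene enters as a numeric
covariate with estimated weight k. The classic ΔΔCT analysis is the
special case k ≡ 1 with no nuisance factors; the reference-free ΔCT
analysis is k ≡ 0. Inference on β_trt uses the classical t statistic with
n − p residual degrees of freedom.

Two properties drive the design:

* **Scale invariance.** OLS t-statistics and p-values of the remaining
  terms are unchanged when any covariate column is multiplied by c > 0
  (k absorbs 1/c), and the treatment p-value is unchanged when the
  response is rescaled. Efficiency differences between genes act exactly
  as such scale factors (log2(1+e) per column), so the treatment p-value
  needs no efficiency correction. `efficiency_scaled_ct` exposes the
  rescaling explicitly for users who want comparable effect sizes.
* **Adaptive use of the reference.** k̂ estimates how much sample-quality
  variation the reference actually shares with the target. An
  uninformative reference gets k̂ ≈ 0 instead of injecting its noise into
  the contrast.

Estimates are in CT units (one unit = one log2-fold change only when
e = 1); fold change 2^−ΔΔCT is a separate, explicit back-transform and all
testing stays on the log scale.

## Classic methods and conventions

ΔCT_i = CT_target,i − CT_reference,i; ΔΔCT = mean(ΔCT | treated) −
mean(ΔCT | control), so a *positive* ΔΔCT means *down*-regulation
(fold change 2^−ΔΔCT < 1). Group comparisons use the pooled-variance
(Student) two-sample t — exact at these tiny group sizes under Gaussian
errors, and algebraically identical to the two-group OLS fit — with Welch
behind a flag; paired designs use the one-sample t on within-subject
differences. A Wilcoxon rank-sum alternative is provided for users who
prefer a distribution-free comparison of the ΔCT distributions; no
default analysis uses it. Degenerate inputs follow a fixed convention:
zero pooled variance with equal means gives statistic 0 / p = 1, with
unequal means p = 0 plus a warning (these arise in simulated corner
cases, never in real CT data).

## Data handling

CT tables are long-format under the hood (sample, subject, treatment,
gene, ct, replicate) with wide/long CSV readers and writers. Missing CT
cells are NaN — never sentinel codes such as 0 or 40, which would corrupt
a linear fit silently — and analyses drop incomplete samples, logging the
count. Technical replicates are collapsed explicitly (mean by default,
median optionally) before any modelling. Gene names match
case-sensitively and exactly. In model formulas the annotation factors
are `Treatment` and `Subject`, case-insensitively; `Donor` is accepted as
a synonym for the subject factor (the donor is the biological subject in
these assays), and coefficient labels keep the user's spelling
(`Donor-KK22F`, `Treatment-ETI`).

Design matrices use the lexicographically first observed level as the
omitted baseline for every factor except treatment, whose baseline is the
user-declared control level. Rank deficiency and n ≤ p are hard errors
(the error names the collinear columns); silent column dropping at n = 10
would quietly change what every term means. The solver is SVD-based least
squares rather than explicit normal equations, for conditioning near
collinearity; standard errors come from σ̂²(XᵀX)⁻¹.

## The simulation framework

Each replicate experiment emulates the paper-scale design: 10 independent
donors, 5 treated and 5 control, one target and one reference gene with
unit-variance CT noise. Margins are standard Gaussian or standardised
exponential (skewness ±2; the left-skewed margin is the exact reflection
of the right-skewed one, so t-based methods give identical rejection
rates on mirrored seeds — a useful internal consistency check). The
target–reference Pearson correlation ρ is produced by linear mixing,
reference = z_R, target = ρ·z_R + √(1−ρ²)·z_e, which is exact for any
margin shape; the trade-off is that the *target's* skewness is attenuated
by the mixing at high ρ, a deliberate choice since the correlation is
specified quantitatively and the skew only qualitatively. Treatment
effects are mean shifts in SD units: `target_effect` on the target
(0 under the null) and `reference_effect` on the reference (1 SD models a
housekeeping gene that responds to treatment). Scored methods: the MLM
treatment term from `target ~ treatment + reference` (3 fitted
parameters, 7 residual df), pooled t on target−reference (ΔΔCT), pooled t
on target alone (ΔCT), all two-sided at α = 0.05.

Defaults are fixed study conditions, not dials: n_per_group = 5, α =
0.05, n_reps = 10,000 (Monte-Carlo SE at a 5% rate ≈ 0.22 pp), power
alternative target_effect = 2.0 SD. The 2-SD alternative reproduces the
qualitative power ordering of the reference experiments (ΔCT best at
ρ = 0, MLM ≈ ΔΔCT ≥ ΔCT at ρ = 0.9, MLM best at ρ = 0.5); absolute power
numbers depend on the alternative's size and are therefore checked as
orderings, not equalities. Replicate r of a scenario draws from
`SeedSequence((seed, r))`, so results are bit-reproducible and
independent of execution order; scenario-grid rows derive their seeds the
same way from the base seed.

What the generator does **not** emulate: technical-replicate noise, plate
or batch effects, donor pairing between treated and control samples
(samples are fully independent), censored/undetermined CT values, and
multi-reference normalisation. Calibration results here therefore speak
to the small-n, independent-sample setting; paired designs and shared
donor effects can only increase the effective target–reference coupling.

## Numerical and degenerate-input choices

* p-values use Student t (never the normal approximation) — material at
  7–8 residual df.
* |ρ| = 1 is allowed (degenerate mixing; target ≡ ±reference).
* α ∈ (0, 1]; α = 1 makes every method reject almost surely (reject iff
  p < α).
* R² reports 1 − RSS/TSS, defined as 1.0 for an exactly-fit constant
  response.
* Rates are exact binomial fractions; the reported Monte-Carlo standard
  error is √(r(1−r)/n_reps).

## Known limitations

* The ANCOVA assumes a common reference weight k across groups and
  homoscedastic Gaussian errors; under strongly skewed margins at n = 10
  all three t-based methods run conservative (empirical type I error
  ~3–4.5% at nominal 5%), which the test suite checks as a one-sided
  bound rather than pretending exact calibration.
* Fixed effects only: donors enter as dummies, not random intercepts.
  At 2 samples per donor and 5 donors a mixed model would estimate a
  variance component from almost no information; the fixed-effects fit is
  also what the worked example's published analysis used.
* Effect estimates are in CT units; converting to fold change at e ≠ 1
  requires measured efficiencies (`efficiency_scaled_ct`), which the
  package deliberately does not estimate from dilution series.
* No reference-gene stability selection; choosing the reference is the
  experimenter's responsibility.
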