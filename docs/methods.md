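# Methods

This note documents the statistical models implemented in `polyepi`, the
calibration of the synthetic-cohort generator, and the numerical choices
made where the design was genuinely open.

## 1. Score construction

The raw polyepigenetic score for sample *s* is the unweighted arithmetic
mean of the products w_i * beta_is over the weight-table probes available
in that sample.  Betas are methylation fractions in [0, 1]; weights are
per-unit-beta effect sizes from an external EWAS.  There is no
normalization by the sum of absolute weights: the estimator is the literal
"average of weighted betas", and any uniform rescaling of betas (percent
vs fraction) or of weights is absorbed by the within-cohort
standardization (mean 0, SD 1, sample SD with the n-1 denominator).
Standardization makes the fraction-vs-percent question immaterial for
every downstream analysis, all of which are reported in cohort SD units.

Missing data policy: probes absent from the matrix or missing in a sample
shrink the per-sample denominator; coverage (fraction of weight-table
probes used) is reported per sample.  Default `min_coverage` is 0.95
(warn, or drop/error by configuration); coverage below 0.50 always raises,
because a score computed from fewer than half its probes is not comparable
across samples.  No published missingness rule exists for this estimator,
so the thresholds are package policy.

## 2. Synthetic cohorts

Real cohort methylation is not redistributable, so every analysis is
validated on generated data.  The generator works *score-first*:

1. Draw a latent smoking-methylation burden T per sample on the cohort SD
   scale.  For the cross-sectional cohort, T = mu(group) +
   slope * (pack-years - mean) * [ever-smoker] + e, where the residual SD
   is solved analytically so Var(T) = 1; configured group effects and the
   pack-year slope are therefore recoverable in SD units after
   standardization.  A configuration whose effects explain more than unit
   variance is rejected.
2. Invert to betas through a logistic probe model:
   beta_is = expit(logit(b0_i) + coupling * w_i * T_s + eps_is), with
   baselines b0_i ~ U(0.2, 0.8), weights w_i ~ N(0, 1) (emitted as the
   cohort's weight table) and logit-scale noise eps ~ N(0, sigma_p).
   Averaging w_i * beta_is over probes yields an affinely consistent
   estimate of T, so the standardized measured score converges on the
   standardized burden.

Default coupling/noise for cross-sectional cohorts is 0.2 / 0.5 on the
logit scale.  This keeps single-probe correlations with the burden modest
(roughly 0.2-0.4, as for real smoking CpGs) while the 2623-probe score
retains reliability > 0.99; it also keeps probe-probe correlations small
enough that the expression screen is not flooded by indirect pairs.  At
300 probes (the scale used in the test suite) score reliability is about
0.99, attenuating recovered slopes by about 1%, well inside confidence
intervals at cohort sample sizes.

Cohort sizes and effect defaults mirror the published study conditions:
405/233/165 never/former/current with contrasts 0.45 and 1.65 SD;
pack-years Gamma(mean 11.71, SD 8.65) among ever-smokers with slope
0.07 SD per pack-year; an independent second-hand-smoke indicator
(Bernoulli 0.30) used by sensitivity analyses.

### Twins

Pack-years and the trait each receive additive-genetic (A), shared (C) and
non-shared (E) standard-normal components; MZ pairs share A fully, DZ
pairs with correlation 1/2, giving expected intraclass correlations
a2 + c2 (MZ) and a2/2 + c2 (DZ).  Trait defaults a2 = 0.709, c2 = 0.160;
pack-years a2 = 0.485, c2 = 0.160.  Two optional couplings generate the
discordant-twin structure: a causal within-family effect of pack-years on
the trait (`packyear_effect`, default 0.09 when used) and a loading of the
trait on the pack-years additive-genetic factor (`genetic_confounding`).
The confounding loading inflates the DZ within-pair slope but not the MZ
one (MZ co-twins share A exactly, so it cancels in deviations); 0.244 is
the value for which the pooled within-pair slope is 0.18 at a 56:44 MZ:DZ
pair mix while the MZ-only slope stays at the causal 0.09.  When either
coupling is active the ACE residual is rescaled so the trait keeps unit
variance, which makes the injected slopes exact in expectation; the
trait's total ACE fractions are then approximate rather than exact.

### Mediation (adversity -> smoking -> methylation)

Adversity counts are Binomial(10, 0.15) (a right-skewed 0-10 exposure
sum); each adversity category adds 2.0 pack-years on top of
Gamma(mean 8, SD 6) noise; the burden is slope * pack-years plus a small
independent component (SD 0.1), and only the first `n_causal` = 100 of
1000 probes respond to it.  Two deliberate calibrations:

- probe coupling is 0.5 (stronger than the cross-sectional default):
  the EWAS demonstration needs per-probe effects large enough to clear a
  1000-probe Bonferroni bar at n = 800, and a *moderate* logit range keeps
  the logistic response near-linear, so that conditioning on pack-years
  (a linear adjustment) genuinely nulls the mediated adversity signal --
  with coupling 1.0 the curvature leaks a nonlinear pack-year remainder
  past the linear adjustment and the conditional-independence structure
  the cohort is supposed to embody fails;
- the burden is smoking-dominated (small independent component), so the
  measured score is a tight pack-year proxy (r around 0.95) and score
  adjustment reproduces the pack-year adjustment probe by probe.

With `direct_effect` = 0 the cohort is mediation-only: the adversity EWAS
has hits unadjusted and none after pack-year or score adjustment.

### Two waves

Wave-1 burdens follow the cross-sectional group structure over four
smoking histories (405 never, 143 quit-by-wave-1, 90 quit-between,
165 still-current).  Changes are wave 2 minus wave 1: zero drift for
never-smokers and early quitters, a -0.25 SD recovery for between-wave
quitters, and 0.05 SD per added pack-year for continuing smokers, plus a
0.35 SD direct effect of wave-2 nicotine dependence and 4.6 extra
pack-years for dependent smokers (so the raw dependence contrast is about
0.58 and the pack-year-adjusted one about 0.35).  The non-dependent
pack-year increment mean (5.2) is set so the *overall* current-smoker mean
change, including the dependence components, lands near +0.49 SD.  Organ
damage is driven by the burden change: DLco/VA change at -0.23 SD and
periodontal attachment loss at +0.17 mm per score SD.  The per-pack-year
organ slopes implied by this chain (about -0.012 and +0.009) are smaller
than the separately reported -0.03 / +0.07 per pack-year; one generative
chain cannot satisfy both sets of marginal slopes at once, and the
score-based slopes were kept because the package is score-centric.

### Expression

Probesets (143, mapped to 98 genes) are organized into 14 regulatory
modules containing 47 linked CpGs and 22 linked probesets.  Each module
has an activity factor that loads 0.4 on the smoking burden and is
otherwise independent; member CpGs add the factor to their logits
(loading 1.0) and member probesets draw 0.75 of their SD from it.  This
reproduces the two key phenomena jointly: linked probesets are
discoverable by a transcriptome-wide association with the score (through
the burden loading), and the methylation-expression pair correlations
survive within never-smokers and current-smokers separately (through the
smoking-independent factor variance).  The round-robin module assignment
yields 76 designated pairs; the number of screen hits is emergent, not a
target.  One showcase CpG is placed 124 bp upstream of its module's gene
start, the canonical cis example; all other linked CpGs land at random
genomic positions and are almost surely trans.

### What the generator does not emulate

Probe-level genomic annotation (island/shore context), batch and
cell-composition effects, array measurement error structure, non-additive
genetic variance, attrition, and the discreteness of real pack-year
reporting.  Passing tests therefore certify the estimators and their
contracts under the declared generative structure, not robustness to those
real-data features.

## 3. Estimators and inference

- **Contrasts, trajectories, dose-response, dependence contrasts**: single
  linear models with group indicators (statsmodels OLS), Wald intervals
  with normal quantiles at two-sided alpha = 0.05 throughout; cluster-
  robust (sandwich) covariances by family where a cluster id is supplied.
- **AUC**: midrank Mann-Whitney; variance by DeLong's placement-value
  estimator; interval clipped to [0, 1].
- **GEE**: Gaussian identity link, exchangeable working correlation by
  default (independence reproduces OLS point estimates exactly), robust
  standard errors always on (statsmodels GEE).
- **ICC**: double-entry Pearson correlation (each pair enters in both
  orders), symmetric in twin labelling by construction; Fisher-z interval
  with the number of pairs as effective sample size.
- **Falconer**: a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ;
  negative components truncated at zero and renormalized, flagged.
- **ML ACE**: joint bivariate-normal likelihood over MZ and DZ pairs on
  internally standardized data; the common scale parameter is profiled
  out in closed form, leaving a 2-D simplex optimization (Nelder-Mead
  started from the Falconer point).  Profile-likelihood 95% CIs by
  bisection on the chi-square(1) cutoff; pair-resampling bootstrap
  available.  Boundary solutions (any fraction < 1e-3) are flagged.
- **Between/within**: outcome on pair-mean and pair-deviation predictors
  simultaneously, cluster-robust by pair; for complete MZ pairs the within
  coefficient is algebraically the pair-difference regression through the
  origin (asserted in tests).
- **EWAS**: vectorized multi-outcome OLS (one design, thousands of probe
  outcomes); classical t(df) p-values match statsmodels per-probe fits to
  machine precision, one-way cluster-robust covariances with the standard
  small-sample factor and t(G-1) reference when clustering is requested.
  Significance is Bonferroni alpha / (probes tested); zero-variance probes
  are dropped and logged; an M-value transform is optional (betas are the
  default scale).
- **Screen**: per-stratum Pearson correlations over the full probe x
  probeset grid via standardized matrix products; the per-test threshold
  is computed in exact rational arithmetic as alpha / (n_probes x
  n_probesets) and only rounded for display.  A pair is a hit only if it
  clears the threshold in both strata.  Spearman available by
  rank-transforming rows first.
- **Sensitivity**: residual-on-residual partial correlations with n - 3
  degrees of freedom; pairs whose methylation probe is collinear with the
  covariate are skipped and recorded; the headline statistic is the
  Spearman correlation between adjusted and unadjusted coefficient
  vectors.

## 4. Numerical and design choices

- Two-wave standardization anchors both waves to the wave-1 mean/SD, so
  changes read in baseline SD units (pooled standardization available).
- Change is defined as wave 2 minus wave 1; analysis subsets (ever-smoker,
  pack-year accumulator) are explicit boolean masks supplied by the caller.
- p-values accompanying Wald intervals use the normal reference,
  consistent with the intervals; EWAS/transcriptome p-values use t(df) to
  match the exact least-squares fits they summarize.
- ACE likelihood guards: correlations clipped below 1, variance floored at
  1e-9; profile CIs fall back to the [0, 1] bounds when the cutoff is not
  bracketed (boundary cases).
- The weight-table loader validates uniqueness and finiteness row-by-row
  and names offending rows in errors; beta matrices are validated to
  [0, 1] with missingness allowed.

## 5. Problem sizes

The test suite runs cohorts at 300 simulated probes (score reliability
about 0.99) with full published sample sizes, 100-replicate coverage
checks, and twin cohorts up to 5000+5000 pairs; the acceptance script uses
the full 2623-probe panel for the cross-sectional cohort and screen,
default-sized twin cohorts (625 MZ + 491 DZ pairs) for ICCs, 6000+6000
pairs for the ML ACE fit and
about 14,000 pairs for the between/within slopes.  These sizes were chosen
so Monte-Carlo error is small relative to the quantities being recovered.

## 6. Known limitations

- The ML ACE model fits A, C, E only (no dominance/ADE, no sex limitation,
  no extended pedigrees).
- GEE supports the Gaussian identity link only.
- The EWAS adjusts for supplied covariates linearly; no cell-composition
  or surrogate-variable correction.
- cis/trans annotation is relative to a single gene-start coordinate per
  gene (no strand-aware TSS logic, no re-annotation of probes to genes).
- Single-probe scores degenerate correctly (the standardized beta of that
  probe), but probe-level QC/normalization is out of scope: inputs are
  assumed to be preprocessed beta values.
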