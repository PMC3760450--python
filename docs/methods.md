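# Methods

## The problem

In a toxicant exposure time course on synchronized *C. elegans* cultures,
expression changes arise from two entangled sources: direct transcriptional
responses to the compound, and a toxicant-induced slowing of larval
development. Because a large fraction of the transcriptome ramps with
developmental stage, a delayed culture compared with a control at the same
clock time shows thousands of "differentially expressed" genes that are
nothing but the developmental program read at a shifted phase. chronostage
implements the analysis strategy for this situation: estimate each sample's
developmental age molecularly (Predicted Age, PA), then test exposure effects
with the age as a covariate.

## Predicted Age

**Developmental screen.** Using only unexposed, continuous-regime samples, a
one-way ANOVA over harvest time is run per probe, with Benjamini–Hochberg
step-up control across all probes. Probes with FDR < 0.001 whose harvest-mean
log2 expression changes at least 1.8-fold from time zero to some harvest form
the developmentally regulated set.

**Per-harvest staging panels.** For each harvest *t*, probes are kept when
their harvest-mean expression changes at least 2-fold over the window of the
two preceding harvest intervals and responds linearly there (r² > 0.95 of the
harvest means regressed on time). The r² is computed on harvest means rather
than replicate-level values: with realistic replicate noise the
replicate-level r² of a perfectly linear probe rarely reaches 0.95
(r² = s²Var(t)/(s²Var(t)+σ²)), so a replicate-level rule would empty the
panel; the mean-level rule measures the linearity of the trajectory, which is
what the filter is for. For the first post-baseline harvest only a single
preceding interval exists; the window is truncated with a warning and the
2-fold requirement pro-rated by window span relative to two nominal
(median-spacing) intervals, so that early samples — whose PA is needed as a
covariate at the earliest test point — can still be staged. Full windows keep
the exact 2-fold rule.

**Calibration and inversion.** Per panel probe, ordinary least squares of
log2 expression on harvest time over the unexposed continuous samples of the
window gives x = a + b·t. Probes with |b| < log2(1.2)/26 per hour are dropped
— inverting a near-flat line turns noise into unbounded age error. A sample's
apparent age under one probe is the inverse prediction (x − a)/b; the PA is
the unweighted mean of the apparent ages over the panel and the reported
dispersion is their standard deviation. Extrapolation beyond the calibration
window is permitted but flagged. Regressing expression on time and inverting
(rather than regressing time on expression) keeps a single calibration model
per probe and is the standard treatment of inverse prediction from a
calibration line.

**Purging toxicant-responsive probes.** The panel must not contain probes
that respond to the toxicant directly, or exposed samples would be staged
with contaminated clocks. A delay-unaware exposed-vs-control screen cannot
identify them: under a delay every sloped developmental probe differs from
control at matched harvest, so such a purge evicts essentially the whole
panel. chronostage therefore stages once with no exclusions, flags probes
passing a lenient PA-adjusted screen (exposure term p < 0.01 and 1.5-fold
adjusted contrast at any continuous-arm harvest), and restages with those
excluded (one bootstrap iteration by default).

**Delay estimate.** At each harvest the developmental delay is the mean
control PA minus the mean exposed PA.

## Delay-adjusted differential expression

Per harvest and per probe, the ANCOVA

    log2 x = b0 + b1·PA + b2·I(exposed)

is fit on the exposed samples of that harvest plus the unexposed samples of
that harvest and the preceding one (sham-washed controls for the washout arm
where available, continuous controls otherwise). b2 is the adjusted log2
fold change and is tested two-sided with n − 3 residual degrees of freedom.
Strict significance requires p < 1e-4, |b2| ≥ log2(1.8), and the range
guard: the mean exposed expression on the linear scale must lie at least
1.2-fold outside the min–max envelope of the included control samples. The
guard protects the linear model against non-linear time trends across the
harvest interval; notably, when the delay approximately equals the grid
spacing it also suppresses most delay artifacts on its own, because a
delayed sample recapitulates the preceding control harvest and thus sits
inside the envelope. The cascade summary therefore reports both the p+fold
sets and the final guarded sets.

Fitting is per probe (no variance pooling or moderation); the fixed p < 1e-4
cutoff is primary. Recovery analysis applies the same strict rules in the
8 h-washout arm; a probe is *washout-unique* when strict-significant at a
washout harvest without even passing the lenient rules (p < 0.01, 1.5-fold,
uncorrected, no guard) at any continuous-arm harvest. Delay-resistant
developmental genes are those within 1.2-fold of control at every harvest
while stepping at least 1.8-fold between some pair of consecutive control
harvests in the 8–26 h range.

## Enrichment

Gene-set over-representation uses the upper-tail cumulative hypergeometric
probability P(X ≥ k) — the observed overlap included — with BH FDR applied
within each collection and a 0.01 cutoff. Probes are mapped to genes under
the single-gene rule (multi-mapping and unmapped probes discarded); gene-level
collections should be tested against the gene-level population and
array-derived (probe-level) collections against the probe-level population.

## The synthetic-data generator

The generator's defaults are the study conditions: three concentrations
(0, 0.6, 15 µM), continuous/2 h-washout/8 h-washout regimes with sham washes,
harvests at 0, 2, 8, 14, 20 and 26 h, four biological replicates, and no
washout-arm samples before the washout — 37 design cells, 148 samples.
Probe classes: developmental (log2 x = c + s·a(t), slopes uniform on
±[0.06, 0.25] log2/h, 10 % saturating to give the linearity filter something
to reject), toxicant-responsive (effects ±1.5 log2 units on average with
staggered onsets so that counts grow with harvest time; effects decay
exponentially after washout with a 2 h half-life; a 5 % minority is induced
only after washout, modelling recovery-specific responses), both, null and
absent (background with Present = False). The exposed-culture delay is
d(t) = δ·min(t, t_washout, w)/w with δ = 6 h and accrual window w = 8 h, so
continuous and 8 h-washout arms are delayed alike — development is
vulnerable early in the exposure — while the 2 h washout accrues only 1.5 h.
The low dose has zero potency by default and sham washes are undelayed
(their handicap is a free parameter, default 0). Noise is homoscedastic
Gaussian on the log2 scale, SD 0.15.

What the generator does *not* model: probe-level (PM/MM) signal formation,
batch/culture-day effects, heteroscedastic or intensity-dependent noise,
dose–response shape beyond two levels, and biological desynchronization
within a culture. Passing tests therefore demonstrate the statistical
properties of the procedures under the designed conditions, not performance
on raw array data.

## Numerical choices and edge cases

- ANOVA/OLS are vectorized over probes; probes with zero variance get p = 1
  in the screen, and an exact-fit ANCOVA (zero residual variance) reports
  p = 0 for a nonzero contrast, p = 1 otherwise.
- Quantile normalization maps average ranks onto the row-means of the sorted
  columns by linear interpolation, so ties receive the mean of the tied
  targets; the transform is idempotent.
- BH adjustment is the step-up minimum construction, capped at one.
- Rank-deficient ANCOVA designs (PA collinear with exposure) raise an error
  naming the harvest rather than returning silent garbage.
- PCA fixes each component's sign by making its largest-magnitude loading
  positive, so scores are reproducible run to run.
- PA-matched ratio columns pair each exposed condition with the control
  condition of nearest mean PA, tolerance 2 h (conditions without a match are
  skipped with a warning); heatmap row ordering, where requested, is
  average-linkage hierarchical clustering on Euclidean distance — an explicit
  choice, recorded here because several conventions are equally defensible.

## Problem sizes used in the checks

The bundled test suite and the acceptance script run the full pipeline on
2,000-probe simulations (20-seed sweeps for the staging and delay-recovery
properties, a 5-seed sweep in the script) and a 25,000-probe null simulation
giving 125,000 pooled probe-tests for the rejection-rate calibration. These
sizes give the statistical resolution the assertions need — e.g. a 3-SE
binomial band around 1e-4 requires ≥ 1e5 tests — while a complete run stays
in the tens of seconds.

## Known limitations

- Staging quality at the 0 h and 2 h harvests is intrinsically lower: the
  truncated window supports only two time levels, so its panel is selected
  without a meaningful linearity rule and calibration slopes are noisier.
- The lenient purge criterion for "toxicant-responsive" panel probes is a
  design choice; with very strong, pervasive direct effects a single
  bootstrap iteration may leave residual contamination (increase `n_iter`).
- Inverse prediction is slightly biased when calibration slopes are small
  relative to their standard errors; the slope guard bounds but does not
  eliminate this.
- Per-probe ANCOVA with n ≈ 12 samples has limited power for effects below
  ~1 log2 unit at p < 1e-4; the cascade is deliberately specific, not
  sensitive.
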