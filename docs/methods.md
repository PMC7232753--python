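# Methods

## Model and estimands

Each record is one infected host: a host-type label, a strain label, a
microbial density (raw cfu), and either a continuous health score or a 0/1
survival indicator. Within a (host type, strain) group, health is modelled
as linear in density on the analysis scale,

    health = a + b·c + ε,   ε ~ N(0, σ²),

with intercept *a* (vigour), slope *b*, and group mean density *c̄*. The
slope and the mean density are the two estimands everything else is built
from: across host types they are tolerance and (inverse) resistance; across
strains, benevolence and proliferation. Virulence is reported as the signed
product *b·c̄* — negative values mean net harm at typical densities; we
deliberately do not fold it into a positive "harm magnitude", so that
benevolent microbes (b > 0) get positive virulence-scale scores that read as
benefit.

## Density scale

Analyses run on a configurable density scale: raw cfu or `log10(cfu + 1)`
(default). Colony counts commonly span orders of magnitude, and
health-vs-density plots in this literature are conventionally on log
density; the +1 offset keeps uninfected hosts (density 0) in the data at
log-density 0, where they inform the intercept. All fitted quantities
(*a*, *b*, *c̄*, virulence) are on the configured scale, which every result
object records. Uninfected hosts are retained by default and identifiable
via `ExperimentRecord.uninfected`.

## Fitting and tests

All models are ordinary least squares (continuous outcomes) or binomial
logit GLMs (survival), fitted with statsmodels on explicitly constructed
design matrices using treatment contrasts with the alphabetically first
level as reference. Coding never affects interpretation: every fit also
reports per-group intercepts and slopes as linear combinations of the
full-model coefficients, with standard errors from the coefficient
covariance. For the saturated interaction model these per-group lines are
algebraically identical to independent per-group least-squares fits, which
the test suite verifies against a `numpy.linalg.lstsq` oracle.

* **Density variation** (`density ~ group`): omnibus one-way F computed from
  the between/within sum-of-squares decomposition. Zero within-group
  variance gives NaN p-values with a `zero_within_group_variance` flag
  rather than a spurious 0.
* **Slope variation** (`health ~ group * density`): the grouped interaction
  is tested by extra-sum-of-squares F against the additive model. For two
  groups this is exactly the pooled-variance t-test of the slope contrast
  (verified in tests). Density is not mean-centred; main effects are
  interpreted only through the per-group summaries, which avoids centering
  ambiguity in unbalanced designs.
* **Combined factorial**: the density model screens the host × strain
  interaction first; if significant at α it is retained and the result is
  flagged (`outcome_depends_on_host_strain_combination`), otherwise the
  additive model is reported. Per-factor tests are model comparisons
  (Type-II-like), chosen because classical sequential sums of squares are
  order-dependent in unbalanced designs.
* **Binary outcomes**: same term structure on the logit scale; the
  interaction is a likelihood-ratio χ² against the additive model.
  Per-group slopes are log-odds per unit density and labelled as such.
  Complete separation (monotone likelihood — detected via non-convergence,
  exploding coefficients, or fitted probabilities saturating at 0/1) flags
  the result and falls back to a small-L2-penalised refit for point
  estimates; p-values are withheld (NaN) in that case rather than reported
  from an invalid likelihood.
* **Quadratic extension**: adds density² and its group interaction; the
  curvature evidence is the F comparison of quadratic vs linear interaction
  model — the finite-sample Gaussian equivalent of a likelihood-ratio
  comparison.

Records with missing density or outcome are excluded and counted
(`n_excluded`); there is no imputation. Exact-fit data (zero residual
variance) produce NaN p-values with a degeneracy flag when the comparison is
uninformative, and p = 0 when the full model fits exactly but the reduced
model cannot.

## Direction calls and factor classification

A group's effect is called benevolent/malevolent only if its slope differs
from zero in a two-sided t test at α (default 0.05) within the observed
density span; a point-estimate-only mode (α = None) is available because the
defining conditions are sign conditions, and some users may want the raw
direction. α is configurable everywhere.

Wild-type/knockout classification runs the slope test and the density test
with group ∈ {wt, ko}. The two tests address distinct hypotheses, so no
multiplicity correction is applied by default; a Bonferroni flag halves α
for users who prefer a family-wise guarantee. "Pure" means exactly one test
significant. Because non-significance is weak evidence of absence, a purity
claim is always accompanied by the non-significant test's p-value and a
minimum detectable effect: the difference detectable with ~80% power at the
observed standard error, `(z_{1−α/2} + z_{0.8})·SE`. For host factors, the
tolerance call requires the wild-type slope to be shallower toward harm
(b_wt > b_ko with non-positive slopes); when the two slopes straddle zero
the direction of "shallower" is undefined and the call is flagged
ambiguous instead of made.

## Diagnostics

* **Density overlap**: for each group pair, intersection-over-union of the
  observed min–max density ranges on the analysis scale. This is a
  deliberately assumption-free interval measure rather than a distributional
  overlap; the default threshold 0.5 is a declared package convention, not
  an empirical constant. Pairs below threshold downgrade slope comparisons
  on the same data to "unreliable" (flag on the FitResult) without
  suppressing them — slope differences estimated over barely-overlapping
  density ranges can be artifacts of extrapolation.
* **Linearity**: wraps the quadratic-extension fit and reports the curvature
  p-value, per-group quadratic coefficients, and an advisory recommending
  the quadratic model when curvature is detected.

Diagnostics never mutate records, and fits are identical whether or not
diagnostics run.

## Synthetic data

The simulator inverts the analysis model. Densities are drawn per cell from
a normal distribution on the analysis scale — i.e. roughly lognormal cfu
under the default scale, matching microbiological convention — truncated at
zero by redraw; truncation affecting > 0.1% of draws is logged because it
shifts the realised mean. Continuous health is the cell's line (plus an
optional quadratic term) with i.i.d. Gaussian noise; binary survival is
Bernoulli with logit a + b·c, making the generative parameters log-odds.
Scenario seeds are mandatory and fully determine the dataset (bit-identical
CSV for a fixed seed and library versions).

Standard conditions used by the presets and throughout the validation:
baseline health a = 10, health noise σ = 1, density spread sd = 1 on the
log10 scale, n = 50 hosts per cell, and unit (1.0 log10 or 1.0 slope)
offsets where a difference is intended — effect sizes a well-powered
single-lab infection experiment is designed to resolve. `fig1_resistance`
uses mean log densities {2, 3.5, 5} (sd 0.75) with a common slope;
`fig1_tolerance` slopes {−0.5, −1, −1.5} at a common mean; `fig2_strains`
spans a benevolent (b = +1), neutral (b = 0), and malevolent (b = −1) strain
with mean densities 3 < 4 < 5; the `knockout_pure_*` presets change exactly
one trait of the wild type, and `knockout_mixed` raises density by 1.0 while
lowering the slope by 0.8.

What the generator does **not** emulate: within-host dynamics (density is a
single endpoint), correlated health/density measurement errors,
heteroscedastic noise, non-normal density distributions, and block or batch
structure. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated generative model, not that any
particular real system satisfies it — the diagnostics exist precisely
because real data may not.

The Monte-Carlo layer (`power_sweep`) reparameterises a scenario along a
grid (n, noise, slope or density offsets, or any single cell field), and
reports rejection fractions with binomial standard errors; all replicate
seeds derive from the scenario seed.

## Numerical choices

* Degenerate p-values (zero residual variance where the comparison is
  uninformative) are NaN plus a flag, never 0 or 1.
* Exact-fit tolerances scale with the total sum of squares
  (`1e-12 · (TSS + 1)`).
* The virulence identity v = b·c̄ is enforced at construction to 1e-12
  relative tolerance.
* Interval overlap of two zero-length ranges at the same point is defined
  as 1 (identical), and a zero-length range against a proper interval gives
  0 area-overlap with a degeneracy flag.
* Slope-direction tests use the t reference when residual degrees of freedom
  are available, else a normal approximation.

## Validation summary

The test suite checks, among others: oracle equivalence of saturated-model
per-group lines vs independent fits on a zero-residual fixture; agreement of
the one-way omnibus test with a hand-rolled sums-of-squares decomposition
and of the two-group interaction F with a separate-fits slope-contrast
t-test; nominal type-I error (99% binomial CI around α over 2000 null
replicates) for all six tests; slope bias < 0.05 with 93–97% CI coverage
over 1000 replicates at Δb = 1, σ = 1, n = 50; power monotone in n and
effect size; ≥ 90% exact-label accuracy for the pure-factor presets over
500 replicates with ≤ 10% false calls under the null; and byte-level
simulation determinism. `scripts/acceptance.py` recomputes these quantities
(at 300–1000 replicates, sized to keep a single-CPU run under a few
minutes) from any seed.

## Known limitations

* No mixed-effects or phylogenetic models: strain relatedness is ignored, so
  the tests demonstrate presence of variation, not heritability.
* Density is the only microbial-fitness proxy; transmission and
  epidemiological fitness are out of scope.
* The overlap diagnostic flags risky comparisons but applies no bias
  correction.
* The separation fallback is a ridge-penalised GLM, adequate for point
  estimates but not for inference; Firth-type bias reduction would be the
  classical alternative.
* Purity calls inherit the usual asymmetry of significance testing: a
  non-significant second test bounds, but does not exclude, a small second
  effect (hence the reported minimum detectable effect).
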