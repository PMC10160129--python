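# Methods

## Scope and working model

mrkit implements two-sample summary-data Mendelian randomization. The
analysis unit is a set of J independent instruments with exposure
associations (bx_j, se_xj) and outcome associations (by_j, se_yj) on the
log-odds scale, estimated in non-overlapping samples. The identifying
assumptions are the usual instrumental-variable triple — relevance,
independence from confounders, and exclusion (no horizontal pleiotropy) —
with each sensitivity estimator relaxing exclusion in a different
direction.

## Estimators

**IVW (primary).** Zero-intercept weighted regression of by on bx with
weights se_y^-2, equivalent to the inverse-variance-weighted mean of Wald
ratios. Standard errors use the multiplicative random-effects dispersion
φ = max(1, Q/(J−1)): heterogeneity inflates the SE, and the floor at 1
prevents anti-conservative precision when the data are under-dispersed.
A single instrument falls back to its Wald ratio with the first-order SE
se_y/|bx|; the second-order (weak-instrument) term is omitted because
instruments are selected at p < 5e-8, where it is negligible.

**Cochran's Q.** Q = Σ w_j (by_j − θ̂ bx_j)², chi-square on J−1 df.

**MR-Egger.** Instruments are first oriented so every bx_j ≥ 0 (joint
sign flips leave the fit invariant); the weighted regression then gains
an intercept whose distance from zero is the directional-pleiotropy test
(valid under the InSIDE assumption). Residual dispersion on J−2 df,
floored at 1 as for IVW.

**Weighted median.** Wald ratios ordered ascending; the estimate
interpolates the inverse-variance-standardised cumulative weights
p_j = (S_j − w_j/2)/S_J at 1/2. The SE is a parametric bootstrap
(default 1000 seeded resamples of (bx_j, by_j) from normals with the
stated SEs); identical seeds give bit-identical results.

**MR-PRESSO.** The observed global statistic is the leave-one-out
residual sum of squares RSS = Σ_j w_j (by_j − θ̂₋j bx_j)². Its null
distribution comes from K (default 1000) parametric simulations centred
at (bx_j, θ̂₋j bx_j); the global p-value is the add-one empirical upper
tail, so it is bounded below by 1/(K+1). Outlier flagging is staged on a
significant global test and then compares each SNP's observed
contribution with its simulated distribution at the Bonferroni level
0.05/J. Two deliberate choices here: (i) the per-SNP p-value is the
plain empirical fraction, not the add-one version — the add-one floor
1/(K+1) exceeds 0.05/J once J ≳ K/20, which would make outliers
undetectable at realistic instrument counts; (ii) staging on the global
test keeps clean data from being searched for outliers, so the false
flag rate on homogeneous sets is near zero. The distortion p-value
contrasts the raw-minus-corrected shift with shifts obtained by removing
equally many randomly chosen SNPs in the simulated datasets; it is
reported but never acted on.

**p-values and intervals.** All p-values use the normal reference
distribution and all 95% intervals are estimate ± 1.96·SE. At the
instrument counts this package targets (~100) the difference from
t-based references is a few percent of the nominal level; small-J users
comparing against t-based software should expect slightly smaller
p-values here.

## Multivariable MR and mediation

`mvmr_fit` is the zero-intercept weighted regression of by on the matrix
of exposure/mediator associations (weights se_y^-2, dispersion floored at
1 on J−k df, collinearity rejected above condition number 1e8). With one
column it reduces exactly to IVW.

The two-step decomposition multiplies the univariable exposure→mediator
effect α by the mediator→outcome effect β from the joint model; the
proportion mediated is α·β divided by the univariable total effect, on
the log-odds scale, and is intentionally unclamped — negative values and
values above 1 are legitimate outputs, not errors. With several
mediators the combined indirect effect sums the per-path products using
jointly adjusted β's; this summed-joint-products rule is one of several
defensible definitions of a combined proportion and is stated here
because the combined column is not generally the sum of single-mediator
proportions. No confidence interval is attached to the proportion; the
delta-method SE of the indirect effect is reported for diagnostics only.

Instrument pooling for the joint model takes the union of each trait's
genome-wide-significant SNPs, aligns every table to the first exposure's
effect alleles, and drops any SNP missing from (or unalignable in) any
constituent GWAS — the simplest defensible rule in a two-sample setting
without proxy look-up.

Across outcome cohorts, the pipeline fits the joint model per cohort,
pools the direct and mediator coefficients by fixed-effects
meta-analysis, and applies the product rule once against the pooled
total effect.

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped
allele order negates the outcome beta and complements its frequency;
strand mismatches are resolved by complementing the outcome alleles once
(a config switch drops them instead); palindromic (A/T, C/G) SNPs are
oriented by comparing minor-allele status across studies and dropped as
ambiguous when the relevant frequency lies strictly inside (0.42, 0.58)
or either frequency is missing. The frequency used for the ambiguity
rule is the outcome's when present, else the exposure's, because outcome
tables are the heterogeneous ones in a multi-cohort screen. Every input
instrument is accounted for (retained + missing + palindromic-ambiguous
+ mismatch = input), and harmonizing an already-aligned pair is a no-op.
Duplicate SNP identifiers within a table keep the first occurrence.
Instrument selection applies the strict threshold p < 5e-8 and, when a
pairwise r² lookup is supplied, greedy pruning in ascending-p order
(ties broken lexicographically) at r² > 0.01; without a lookup the table
is treated as pre-clumped.

## Meta-analysis and multiplicity

Per-outcome cohort estimates are pooled by fixed-effects inverse-variance
weighting; across-cohort heterogeneity is Cochran's Q on k−1 df. The BH
step-up adjustment runs over the family of pooled p-values (one per
outcome); adjusted p < 0.05 is *significant*, nominal p < 0.05 with
adjusted p ≥ 0.05 *suggestive*, else *null*. The boundary q = 0.05 is
deliberately not significant. Sensitivity-estimator p-values are
reported unadjusted.

## Synthetic data generator

The generator works directly on the summary scale: no individual-level
genotypes. Per SNP, MAF ~ U(0.05, 0.5) and the GWAS standard error is
1/√(2·n·maf(1−maf)); observed betas add independent normal noise with
that SE in the exposure and in every outcome cohort (the two-sample
assumption). Defaults emulate a large liability screen: J = 98
instruments, exposure n = 807,553, outcome effective n = 100,000 per
cohort, mediator n = 700,000, 2–3 cohorts per outcome.

True instrument strength is drawn as a z-score uniform on (8, 40). Two
consequences are intended. First, every instrument's expected p-value is
far below 5e-8, so enforcing significance needs no rejection sampling
and selection on the observed p-value introduces no winner's curse
(a `winners_curse`-style regime can be emulated by narrowing `z_range`
toward the threshold). Second, the regime keeps weak-instrument
regression dilution — which the first-order Wald SE does not correct —
an order of magnitude below the Monte-Carlo resolution of the
calibration studies, so bias measurements reflect the estimators rather
than instrument strength. Alleles are random with a ~1/3 palindromic
rate, and outcome tables independently scramble allele order and strand,
so the harmonizer is exercised on every run.

Pleiotropy scenarios: `none`; `balanced` (zero-mean normal α_j);
`directional` (mean μ relative to the exposure-increasing allele, since
a sign-agnostic constant would cancel across randomly oriented
instruments); `inside_violation` (α correlated with instrument
strength). With `scale_by_se` the spread is expressed in units of each
SNP's outcome SE — exactly the multiplicative over-dispersion model the
estimators assume.

What the generator does **not** emulate: LD between instruments (they
are independent, as after clumping), sample overlap between exposure and
outcome GWAS, case-control imbalance beyond an effective sample size,
allele-frequency differences between populations, and genuinely additive
pleiotropic variance mixed with heterogeneous precision (see
limitations). Passing tests therefore validate the estimators under
their stated assumptions, not robustness to these real-data features.

## Validation studies and their designs

All studies live in `mrkit.validation`, are fully seeded
(SeedSequence-spawned child seeds), and are the quantities
`scripts/acceptance.py` reports.

* **Calibration** (500 replicates, θ = 0.3, J = 98): mean bias is
  compared in units of the Monte-Carlo SE of the mean; CI coverage
  should sit in the low-to-mid 0.9s (φ-flooring makes it mildly
  conservative).
* **Type-I error** (1000 replicates each): IVW at θ = 0; the Egger
  intercept under balanced pleiotropy drawn with `scale_by_se`, the
  model under which the test's null is exactly specified. Under
  *additive* balanced pleiotropy with heterogeneous instrument
  precision, the precision-weighted intercept test is mildly
  anti-conservative (we measure ≈ 0.07–0.08 at nominal 0.05); this is a
  property of multiplicative weighting under model misspecification and
  is listed under limitations.
* **Planted outlier** (100 runs, K = 1000): a 12-instrument panel with a
  10·SE shift planted on the highest-weight SNP. The small panel and
  placement are the point of the design: a single 10·SE outlier shifts
  IVW by roughly 10·w_j·bx_j/√(Σ w bx²) estimator SEs — about 4–5 SEs
  here, versus ~1 SE when diluted across ~100 equal instruments, where
  removing it would change nothing measurable.
* **Mediation recovery** (200 replicates): paths a = 0.2, b = 0.5,
  c = 0.1, true proportion 50%; plus an a = 0 null centring on zero.
* **Family-wise control** (100 replicates): 24-outcome all-null bundles;
  the fraction of families with any BH-significant call sits at the
  nominal 5% (slightly below, by the conservativeness noted above).
* **Bookkeeping and determinism**: harmonization count conservation on
  every bundle, and byte-identical outputs for repeated simulate → run →
  report with fixed seeds.

Replicate counts were chosen to keep the full validation run at about a
minute on one CPU while leaving each rate's binomial noise well inside
the bands being checked.

## Known limitations

* Normal (not t) reference distributions throughout; material only for
  small instrument panels.
* The Egger intercept test is anti-conservative under additive balanced
  pleiotropy with heterogeneous instrument precision (measured ≈ 0.07 at
  nominal 0.05 under the generator's default MAF spread); calibration is
  exact under the multiplicative model.
* Proportions mediated are point estimates; no interval is constructed
  (the delta-method SE of the indirect effect ignores the covariance
  between numerator and denominator).
* No proxy-SNP search, reference-panel clumping, liftover, or sample
  overlap modelling; instruments are assumed pre-clumped when no r²
  lookup is given.
* The MR-PRESSO distortion test's null (random same-size removals in
  simulated clean data) is one reasonable construction among several; it
  is reported for diagnostics only.
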