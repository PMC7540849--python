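# Methods

This note records the models, defaults and numerical choices behind
`pasturepheno`, and what the synthetic experiment does and does not emulate.

## Trial design

The layout is a latinized, resolved incomplete-block design: each of the 10
replicate blocks holds 4 main units (one per nutrient combination LNLP,
HNHP, HNLP, LNHP), each main unit 3 consecutive pots (grass monoculture,
legume monoculture, mixture), each pot 2 half-pots (east/west) carrying one
species each — 120 pots and 240 half-pots at the default scale.
Randomization permutes nutrient combinations over main units and
cultivations over pots, with a greedy latinization constraint: each
nutrient combination occupies each within-replicate main-unit position at
most ⌈n_reps/4⌉ times. This preserves the blocking semantics of the
original latinized layout without reproducing an optimal-design search
engine, whose exact constraints are not published; the constraint used here
is a stand-in. Greenhouse side is assigned positionally (main units 1–2
east, 3–4 west) because the original coordinates are not published; the
fertiliser schedule applies a 33 mg N / 11 mg P baseline to every pot at
DAP 16 and tops up to the treatment totals (N: 33/99 mg, P: 11/33 mg) at
DAP 35.

## Synthetic experiment

Each half-pot grows along a 3-parameter logistic
PSA(t) = A/(1+exp(−r(t−t₀))) over the imaging window DAP 28–70 (43
consecutive days; the window start is a package choice — only the day count
and the final day are fixed by the design). The logistic was chosen for a
closed-form noiseless oracle; the asymptote is parametrized through the
monoculture endpoint target sPSA(70) per (species, N, P) cell, with
defaults equal to the published treatment means (grass 200–528 kpixels,
legume 437–549 kpixels), so the configured values are directly the
quantities the analysis estimates. Mixture halves multiply the endpoint by
a facilitation factor (defaults = the published mixture/monoculture
ratios, 1.09–1.79), making the configured factor the expected relative
yield. Rates and inflection days encode the reported dynamics — grass
faster (r = 0.16/0.13 d⁻¹ for high/low N, t₀ = 45/38) and saturating early
without added N; legume slower and P-responsive (r = 0.115/0.100 d⁻¹,
t₀ = 50).

Noise structure, outermost to innermost:

- replicate, main-unit and pot effects, lognormal on the curve scale
  (log-sd 0.05, 0.06, 0.06) — positive sizes with variance growing with
  the mean;
- a half-pot residual effect with species × nitrogen group standard
  deviations (defaults 14/30/20/26 kpixels for grass-LN/grass-HN/
  legume-LN/legume-HN), ramped linearly across the window. The ramp keeps
  early counts positive, and because the smoother reproduces linear
  functions exactly, the full effect arrives at the DAP-70 endpoint — this
  is the true signal the heteroscedastic residual model estimates;
- multiplicative lognormal day-to-day imaging noise (log-sd 0.12; the raw
  series is visibly noisy, as real pixel counts are), split equally over
  the three camera views;
- a lognormal jitter on r per half-pot (log-sd 0.03) so growth-rate traits
  vary within treatment.

Whether real day-to-day variation is additive or multiplicative is not
observable from the published material; multiplicative was chosen because
pixel counts are positive with mean-dependent spread. Harvest biomass is a
linear proxy of the true endpoint, AGB = c·PSA(70) + pot-shared error
(sd 0.38 g) + half-pot error (grass 0.45 g, legume 0.05 g), with slopes
c = 0.009 (grass) and 0.008 (legume) g/kpixel. The pot-shared term exists
because a purely half-pot error cannot reproduce the observed ordering of
validation r² (grass ≈ 0.85 > whole-pot ≈ 0.77 > legume ≈ 0.67): summing
halves would otherwise always raise r² above both species. Shared soil,
watering, harvest handling and drying make a pot-level error component
physically plausible. With these defaults the synthetic r² falls in
0.81–0.88 (grass), 0.57–0.77 (legume) and averages ≈ 0.83 (whole-pot)
across seeds. These bands are generator sanity checks; the real-data r²
values themselves are not reproducible from simulation.

Shoot N and P concentrations are drawn around the published treatment-cell
means (e.g. grass shoot N 7.0→9.18 mg/g low-N mono→mix, 14.34→18.96 high-N)
with species-level sds; soil extractable N and P are pot-level draws around
level-dependent means (N: 10/3.5, P: 9/3 mg/kg). Attrition mirrors the
published exclusions: one dead grass-monoculture LNLP pot, two clerical
half-pot removals (LNLP and LNHP grass monocultures) and two further
nutrient-only removals, yielding 236 usable harvest and 234 usable
nutrient observations from 240; imaging data are never excluded.

## SET smoothing

The smoother solves min ‖y − f‖² + λ∫f″² with natural boundary conditions
on the observed-day grid, via the banded second-difference formulation
f̂ = (I + λK)⁻¹y, K = DᵀW⁻¹D. λ is solved from trace S(λ) = df by Brent's
method on log₁₀λ with an expanding bracket (trace is continuous and
strictly decreasing from n to 2), to |trace−df| < 10⁻⁶. df = 5 is the
default (moderate smoothing); df = 2 is accepted as the infinite-penalty
limit and returns the least-squares line. Smoothing is per half-pot with
no cross-series pooling; days with missing camera views are dropped from
the fit (never imputed) and duplicate imaging days are averaged.
Extraction interpolates the fitted spline (a natural cubic spline through
the fitted values, so interpolation is exact) at DAP 35, 40, 50, 60, 70.
Smoothing on the raw PSA scale is the default; a log-scale option
(smooth ln(1+PSA), exponentiate) exists because the SET method family
supports both and the published analysis does not say which was used.

RGR is the interval log-ratio divided by the interval length (day⁻¹) by
default. The printed formula omits the division, but the stated unit is
day⁻¹ and the intervals have unequal lengths (5 and 10 days), so the
undivided ratio would not be comparable across intervals; the bare
log-ratio is available by flag. The published table headings give RGR two
different units for the two species; this is treated as a typesetting
inconsistency — RGR here is always per day.

## Mixed model

Fixed effects: overall mean; replicate; greenhouse side; pot half; species;
then a full cultivation × nitrogen × phosphorus factorial per species whose
columns are structurally zero for the other species' observations
(±½ product coding; sum-to-zero replicate dummies; aliased columns removed
by a greedy forward rank sweep so earlier terms of the partition take
precedence). Random effects: main units within replicates and pots within
main units, with independent variances. Residuals are independent normal
with variances in species × nitrogen groups (4 groups of 60 at the default
scale); nested reductions (species only, nitrogen only, homogeneous) are
compared by REML likelihood-ratio tests (χ², df = parameter difference,
α = 0.05, fixed structure held constant for REML comparability), testing
the nitrogen difference first, then the species difference, then both.

REML maximization is over log-variances with L-BFGS-B, an exact analytic
gradient (tr(P V̇) − yᵀP V̇ P y, evaluated through the Woodbury identity or,
when the covariance is block-diagonal over main units, through batched
per-block inverses — the two paths agree to 10⁻¹¹ and the block path is
used automatically when the random-effect structure partitions the
observations), and a small multi-start grid. Convergence is declared at a
projected-gradient norm below 10⁻³ on the −2·log-likelihood scale; in
practice the line search exhausts double precision at norms near 10⁻⁴ on
problems of this size, and the gradient itself is exact to central-difference
accuracy of 10⁻⁸.

Wald F for a term is the quadratic form of its coefficients against their
GLS covariance. Denominator degrees of freedom use the containment
heuristic: per-species factorial columns vary within pots, so they are
tested against the residual stratum, ddf = n − (pots with observations) −
rank of X after sweeping out pot means (115 at the default scale). The
original analysis used a proprietary engine with numerically derived
denominator df; the containment value differs only for borderline
p-values. Hierarchy: the three-factor interaction is always tested; the
two-factor interactions only if it is not significant; a main effect only
if its factor occurs in no significant interaction; suppressed terms are
flagged `nr`.

Estimated marginal means average fitted values over a full reference grid
with equal weights. The half-LSD is t(0.975, ddf) × (mean pairwise SED)/2;
letters come from unadjusted pairwise t-comparisons (LSD-style, matching
the half-LSD error-bar presentation; no multiplicity adjustment is applied,
as none is stated for the original tables).

Overyield significance for a species requires three things: a reported
cultivation-containing term significant in the Wald hierarchy, a
significant mixture-vs-monoculture marginal-mean contrast (the
multiple-comparison step of the original workflow), and the mixture mean
exceeding the monoculture mean. The contrast requirement matters: the
union of gated Wald tests alone is measurably liberal (11–16% null rate in
simulation), while the combined rule holds 2–8% at α = 0.05 with full
power at a 1.5× facilitation factor.

## PCA

Correlation-matrix PCA per species × cultivation subset on nine variables
(four RGR intervals, AG, shoot N, shoot P, soil extractable N and P), after
listwise deletion of the removed nutrient replicates. Components with
eigenvalue > 1 are retained (strict rule with a 10⁻⁹ numerical guard; if
nothing is retained the unrotated solution is reported with a warning).
Varimax rotation is Kaiser-normalized iterative pairwise planar rotation
with the closed-form quartic angle per pair, run until the criterion gain
falls below 10⁻¹⁰; column signs are normalized so each factor's largest
loading is positive. Rotated loadings below 0.30 in magnitude are masked
as not significant. No variable is dropped for low communality. All RGR
intervals are always included for cross-species comparability.

## Problem sizes and operating characteristics checked by the test suite

- Spline smoother vs an independent dense-basis oracle at 10⁻⁶ relative on
  a 43-day noisy logistic series; df = 2 limit vs the OLS line.
- REML vs ANOVA closed forms on balanced one-way layouts and groupwise OLS
  on disjoint heteroscedastic blocks.
- Variance-model selection: with residual sd differing by species only
  (18 vs 36 kpixels) and day-to-day noise at log-sd 0.02 — small enough
  that endpoint residuals follow the fitted residual model — the species
  grouping is selected in ≥ 80% of 100 seeds at the 10-replicate scale.
- Overyield inference: ≥ 90% power per species at facilitation 1.5 and
  ≤ 10% null rate at facilitation 1.0, 100 seeds each at full defaults.
- Recovery at 40 replicates: estimated marginal means recover every
  configured cell endpoint and facilitation factor within 15% relative
  bias over 100 seeds at full default noise. Variance components are
  checked over 200 seeds under a homogeneous-endpoint configuration
  (all targets 500 kpixels, facilitation 1, day-noise log-sd 0.01), where
  the lognormal random effects reduce to a common additive structure and
  each component has a well-defined generating value (pot and main-unit
  variance 900 kpixels²; the four residual group variances as configured).
  Under the full heterogeneous defaults the additive model is an
  approximation to the multiplicative generator: part of the
  multiplicative random-effect variance then appears as residual variance
  in the groups with the most heterogeneous means (up to ≈ +60% in
  simulation). This is a known property of fitting additive mixed models
  to multiplicative growth data, not an estimation error, and it leaves
  treatment-mean inference unaffected.

## Known limitations

- Denominator df are containment-based, not numerically derived; borderline
  p-values can differ from engines using Kenward-Roger-type corrections.
- The generator's multiplicative effects violate the additive LMM's
  variance decomposition when cell means are very heterogeneous (above).
- The simulator does not emulate imaging segmentation error structure,
  environmental drift, or biological nitrogen-fixation dynamics; passing
  tests demonstrate the statistical machinery, not real-data performance.
- The latinization constraint is a stand-in for the unpublished original
  design-search constraints.
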