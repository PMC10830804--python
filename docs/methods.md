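# Methods

## The model hierarchy

All models are simple-structure confirmatory factor models: every item loads
on exactly one factor, all factor pairs are freely correlated, residuals are
uncorrelated.  The hierarchy is derived mechanically from the column names
(`test_facet_item`, or `test_item` for flat pools): a *global* model with
one factor over all items, a *tests* model with one factor per first name
part, and — for three-part names — a *facets* model with one factor per
second name part.  Facet identity is the (test, facet) pair; a facet label
reused across tests is disambiguated with a test prefix.  Non-item columns
are a hard error because every column enters the models.  Factors with
fewer than three items are allowed (they are identified through their
correlations with the other factors) but flagged; a one-item factor is
rejected.

## Estimation

Each model minimizes the normal-theory maximum-likelihood discrepancy

F(θ) = ln det Σ(θ) + tr(S Σ(θ)⁻¹) − ln det S − p,  Σ(θ) = ΛΦΛᵀ + Θ,

with factor variances fixed to 1 (so loadings and latent correlations are
estimated directly), Θ diagonal.  The optimizer (L-BFGS with analytic
gradients) works on an unconstrained reparameterization: log residual
variances, and the correlation matrix through a row-normalized Cholesky
factor (unit diagonal on the triangular factor, rows normalized to unit
length).  Every iterate is therefore admissible — Θ > 0 and Φ a valid
correlation matrix by construction.  Boundary ("Heywood-type") solutions
appear as residual variances indistinguishable from 0 and are flagged with a
warning rather than silently accepted; a singular Φ is flagged the same way.

Numerical choices: gradient tolerance 1e-8, iteration budget 10,000, start
values λ = 0.7, residual variance 0.51, inter-factor correlations 0.3.  The
discrepancy is invariant under rescaling of observed variables, so the fit
runs on the correlation scale of the input and the completely standardized
solution (loadings divided by model-implied item standard deviations) is
reported, together with loadings mapped back to the original item units.
After convergence a factor's sign is flipped when its mean loading is
negative, so dominant loadings are positive while genuinely negative
per-item loadings are preserved.

Missing data: listwise deletion by default (covariance with n−1 denominator
over complete rows), or pairwise-complete covariances with the smallest
pair count reported as the effective n.  Full-information ML is out of
scope.  Standard errors and fit indices (CFI/RMSEA) are not computed; the
package reports the discrepancy value, iterations and convergence per model.

## Center distances

Per item, cd = λ_s²/λ_g² − 1 gated at a ratio of 1, evaluated on **absolute**
loadings.  The signed ratio would zero out precisely the diagnostic case —
an item with a small negative general loading and a small positive specific
loading — that the statistic exists to expose, so the gate uses magnitudes
while the signed loadings are kept in every table.  With this gate the
per-item cd is never negative, so display truncation is a no-op at item
level; the mean center distance averages the gated values (a flag switches
to averaging display-floored values, which coincides under this gate).

The aggregate center distance uses untruncated sums of squared loadings on
both sides and may be negative (a net loss); it is floored at zero only in
the chart layer, where the flooring is flagged in the scene graph.  A
general loading within 1e-6 of zero makes the per-item ratio unbounded; the
value is capped (default 100, configurable) and a warning is emitted rather
than propagating infinities.

Cross-test arrows: facet-pair correlations come from the facets model and
test-pair correlations from the tests model; a pair is flagged when
r_facets > r_tests holds strictly, sorted descending by r_facets.

## Synthetic data

The generator defines a population at the most specific naming level: one
primary loading per item, a valid facet correlation matrix, and residual
variances that make every item variance exactly 1 (responses are
multivariate normal in this unit metric; real data need not be standardized
— the estimator is scale invariant).  Coarser-level "true" parameters are
*derived* by fitting the coarser models to the exact population covariance,
which makes population-implied center distances well-defined and gives the
whole pipeline a noise-free oracle: fitting the facet model to the exact
population covariance must reproduce the generating parameters to 1e-4.

An optional secondary loading per item plants misfitting items.  With pure
simple structure the population test-level loadings are essentially
proportional to the facet-level loadings within a facet, so every item in a
facet has about the same cd and a low-loading item cannot produce the
characteristic mean-vs-aggregate disparity.  A small negative cross-loading
on a facet of the *other* test breaks this proportionality the way real
mis-keyed items do: the item's general loading collapses toward zero while
its facet loading stays small but positive.

`hexaco_like_preset` emulates a pair of correlated personality trait scales:
2 tests × 4 facets × 10 items, heterogeneous primary loadings drawn once
(fixed internal seed) from [0.45, 0.80], within-test facet correlations
around 0.50, and one planted outlier (`H_Sinc_Sinc10`, primary 0.20,
secondary −0.40 on the cross-test facet `Gent`).  The cross-test block of
the facet correlation matrix is a fixed pattern times a scale; the scale is
calibrated by bisection so the population-implied test correlation is
exactly 0.45, the preset's nominal condition.  The pattern ties `Gent`
tightly to three H facets but loosely to `Sinc` (which is what drives the
outlier's general loading negative) and leaves the Fair–Gent correlation
above the test correlation, so the preset, like typical real pools, contains
one cross-test arrow.  The generator emulates clean multivariate-normal
responses with MCAR missingness; it does not emulate ordinal/Likert
response scales, floor/ceiling effects, non-normality, or structured
missingness, so passing recovery tests demonstrate correctness of the
estimation pipeline, not robustness to those features of real data.

Default problem sizes used in the test suite: population (exact-covariance)
fits for oracle checks, n = 10,000 samples of the 80-item preset for
recovery checks (test-level correlation recovered within ±0.03, facet
aggregate cds within ±0.15 of their population-implied values), n = 2,000
for the small 12-item model.

## Chart layout

Charts are laid out as a scene graph of primitives in chart units (one unit
of radial distance = one unit of cd times the layer's axis scale) before any
rendering, so geometry is testable exactly.

* Facet circles sit with their nearest edge at radial distance cd from the
  center, evenly spaced starting at 12 o'clock, clockwise, in data order,
  plus per-factor rotation offsets.  The central dotted circle marks the
  axis: its radius is the largest of 1, 2 or 5 × 10^k not exceeding half
  the maximum displayed cd (0.1 when all cds are 0).
* Default subradius is 0.15 × the maximum facet cd, floored at a quarter of
  the axis tick so circles stay legible when cds are small; overlapping
  circles trigger a warning with a fitting value suggested.
* Correlation values are placed at the midpoints of the factor-pair chords
  in row-major upper-triangle order; overlaps are resolved greedily by
  descending |r|, nudging along the chord perpendicular in alternating
  directions.  This rule is this package's reading of "in order, pairwise
  opposite each other"; other layouts exist.
* Item charts give each facet an angular sector; items are radial rays with
  tip markers at their cd, dotted tick circles repeat at multiples of the
  axis value, and the extent grows to fit outliers.
* Nested charts draw the global facet chart (tests as facets) and plug each
  test's facet chart into its circle.  The test circle radii belong to the
  global layer and are fixed by the data: inner chart extent divided by the
  *automatic* relative scaling (the smallest value ≥ 1 at which the largest
  inner chart fits a reference length of the global chart).  An explicit
  `relative_scaling` rescales only the nested layers — doubling it halves
  all nested radial coordinates — and any value other than 1 triggers a
  reader-information warning; values below the automatic one overflow the
  host circles and are warned with the fitting value suggested.
* The item overview draws one mini bar chart per item (grouped by test and
  facet, subsettable) with one bar per model; heights are squared loadings
  by default (raw loadings on request), colors follow the layer palette
  (global gray, tests light blue, facets darker blue — overridable).
* SVG output is byte-stable for identical scene and configuration (fixed
  hash salt, no date metadata); PDF/SVG stay vector, PNG/JPEG honor `dpi`;
  `zoom_x`/`zoom_y` crop the viewport without rescaling geometry.

## Known limitations

* No standard errors or confidence intervals for loadings, correlations or
  center distances (the published example reports CIs for latent
  correlations without an implementable description of the method).
* No fit indices, robust or categorical estimators, and no user-written
  model syntax; the naming convention is the only model-specification
  mechanism.
* The correlation-value placement rule and the automatic relative scaling
  are this package's own design choices where the chart family's verbal
  description leaves the geometry open.
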