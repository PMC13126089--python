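# Methods

This note documents the models, estimators and design choices behind
`mastsync`, in the order the pipeline runs.

## 1. Synthetic worlds (`mastsync.simulate`)

The generator produces trapping and weather tables with a known causal
chain so every downstream stage can be tested against recoverable truth.

**Geometry.** Two anchor sites are pinned at latitude 40° with longitudes
solved from the haversine formula so their great-circle distance equals
`extent_km` (default 4000 km, matching a contiguous-US span).  A third site
sits ~30 km from the western anchor so the shortest correlogram class is
populated; remaining sites scatter uniformly over the longitude span in a
±4° latitude band.  Defaults: 23 sites.

**Climate field.** Monthly temperature anomalies are multivariate normal
across sites with correlation exp(−d/`noise_range_km`) (default e-folding
1500 km, σ = 0.6 °C).  July additionally carries the dipole mode

    anomaly_July(s, y) += dipole_strength · E(s) · Z_y,

with loading E(s) = cos(π·x_s), x_s the site longitude rescaled to [0, 1]
(a smooth one-parameter sign flip: +1 at the west pole, −1 at the east),
and Z_y i.i.d. standard normal.  Daily values are the site's smooth
latitude/season climatology plus the monthly anomaly plus independent
N(0, 2.5 °C) day-to-day noise; tmax/tmin are the daily mean ± half a
uniform 6–14 °C diurnal range, so tmax ≥ tmin by construction.
Precipitation is gamma daily rain scaled by a spatially correlated monthly
log-factor (so precipitation synchrony also decays with distance).

**Masting and abundance.** The mast crop of year y responds to the July
differential of the two preceding summers,

    M(s, y) = softplus(beta_mast · [July(s, y−1) − July(s, y−2)]),

and consumers respond to the prior year's crop plus the current July
anomaly:

    log λ(s, t) = α₀ + alpha_mast · M(s, t−1) + alpha_july · JulyAnom(s, t).

λ is the expected capture rate per trap night.  Defaults: beta_mast = 1.0,
alpha_mast = 0.5, alpha_july = 0.15, α₀ = −5 (≈ 35 individuals per
site-year at typical effort).  No field estimates exist for how strongly
masting drives abundance at these sites, so the effect sizes are chosen for
testability — strong enough that 10-year annual series carry the dipole
through Poisson counting noise; simulated synchrony magnitudes are
correspondingly higher than typical field values.

**Trapping.** Each site-year draws 4–6 bouts in distinct months of
April–September and 3–8 100-trap grids (three "pathogen" grids run three
nights per bout, the rest one night), giving realistic, heterogeneous
trap-night effort.  3% of trap-nights are non-functional (not set,
disturbed, sprung).  Unique individuals per (site, species, year) are
Poisson(effort · λ · species-factor) — a negative-binomial option adds
overdispersion — with ~30% of individuals recaptured within the year, so
unique-tag counting is non-trivial.  1–3 of the nine focal species occur
per site, with lognormal (σ = 0.2) per-species abundance factors.  A
configurable list of (site, year) gaps emulates COVID-era missing data;
three sites lose 2020 by default.

All output is a deterministic function of the config seed; each stage
draws from its own child stream, so stages can be regenerated standalone.

## 2. Abundance index (`mastsync.trapping`)

Index = unique tagged individuals per (site, species, year) divided by
site-level trap nights.  Design choices:

- **Effort statuses.** Trap nights count rows whose status means "set and
  functional": captures, multi-captures, and set-and-empty.  Not-set,
  disturbed and sprung rows are excluded.  The set is configurable.
- **Tag conflicts** (one tag under two species codes in a site-year) are
  resolved by majority vote; ties exclude the tag.  Both paths are logged.
- **Year qualification.** A year qualifies with ≥ 4 distinct trapped
  calendar months (site-level); a series is retained with ≥ 4 *consecutive*
  qualifying years and truncated to its longest qualifying run, ties
  breaking toward the most recent run (the run is the analysis window).
- **Low-capture rule.** Series whose raw annual captures never exceed one
  individual (with ≥ 2 years of data) are dropped.  The threshold is
  configurable; "never exceeds" is the documented reading of the sparse
  data rule.
- A year with records but zero functional trap nights is treated as
  unsampled, not as zero abundance.
- Site aggregates sum species indices; since species at a site share the
  effort denominator this equals summing counts and dividing once
  (asserted).  Min-max 0–100 standardization is provided for display; it is
  monotone, so Spearman-based results are unaffected.

## 3. Annual climate (`mastsync.climate`)

Daily mean temperature is (tmax + tmin)/2 — the standard proxy when only
daily extremes are available.  Monthly aggregates are the mean temperature
and total precipitation over available days; an empty month is missing,
not zero, and months with < 90% of days present are flagged but used (gaps
should warn, not fail).  The five annual variables are July mean
temperature, June total precipitation, January mean temperature, January
total precipitation, and ΔT₂₋₃ = JulyTemp(t−2) − JulyTemp(t−3), the
mast-seeding surrogate (seed crops in t−1 respond to the differential of
the two preceding Julys; consumers respond one year later).  The daily
series therefore must start ≥ 3 years before the first analysis year
(defaults: weather 2009–2022, analysis 2013–2022).

## 4. Synchrony (`mastsync.synchrony`)

Spearman ρ with average ranks on the shared years of each pair
(pairwise-complete, no imputation).  Pairs with fewer than `min_overlap`
shared years (default 4, mirroring the ≥ 4-year inclusion rule — needed
because missing 2020 data shortens overlaps) or a constant series are
missing, not zero.  Population series are kept at (site, species) level —
never averaged into one series per site.  Site-level matrices (climate
synchrony, distance) are conformed to the series-pair space by lookup;
same-site species pairs receive the site's self-value (climate synchrony 1,
distance 0, proximity 1).

## 5. Correlogram (`mastsync.correlogram`)

Great-circle distances (haversine, R = 6371 km) are binned into half-open
classes [0, 50), [50, 500), [500, 1000), [1000, 2000), [2000, 3000),
[3000, ∞) km.  Same-site pairs are distance-class 0: excluded from the
< 50 km class and summarized separately (mean, median, n).  Each class is
summarized by its median ρ and a seeded percentile bootstrap CI
(default n = 1000 resamples, level 0.95 — the conventional level; the CI
is not forced symmetric).  Significance ⇔ the CI excludes 0.

Numerical choices: the unbounded top class is plotted at the midpoint of
its observed distances; empty classes are reported with n = 0 rather than
raising; labels are sorted internally so results are invariant to input
ordering.  The default bootstrap resamples pair-level correlations i.i.d.,
ignoring the dependence induced by shared sites — deliberately, to mirror
the standard correlogram procedure; a block-by-site bootstrap
(`block_by_site=True`), which resamples sites and weights pairs by drawn
site multiplicities, is available for sensitivity analysis.

## 6. MRM (`mastsync.mrm`)

Matrices are unfolded to their off-diagonal unordered pairs in a canonical
shared order; OLS on the vectorized triangles gives coefficients and R².
Inference permutes the response matrix's rows and columns jointly with the
same random relabeling and refits: per-coefficient two-tailed p =
(#{|b*| ≥ |b_obs|} + 1)/(n_perm + 1), whole-model p likewise on R²
(add-one correction guarantees p > 0 and valid size; response — not
residual — permutation is the classical MRM convention; the two-tailed
|b| convention is documented since one-tailed is also defensible).  For
small label sets `exact=True` enumerates all n! permutations, used by the
tests as an exactness oracle.  Missing pairs are deleted case-wise; after
each permutation the refit uses the pairs whose permuted response is
present (matrices from the default pipeline are complete, so this matters
only under missing-data configurations).  Collinear predictors (condition
number > 1e8) raise, naming the most correlated pair.

Proximity = 1 − d/d_max with d_max the largest observed between-site
distance (most distant pair → 0, same-site pairs → 1).  Same-site series
pairs are included by default (proximity 1, climate synchrony 1);
`exclude_same_site_pairs` masks them for sensitivity analysis.
Coefficients are reported on the raw synchrony scale, with standardized
(beta) coefficients alongside.

The four-model suite: space-only (proximity), direct climate (JulyTemp_t,
JunePrecip_t, JanuaryTemp_t, JanuaryPrecip_t), indirect climate (ΔT₂₋₃),
and saturated (all six predictors), yielding a 12-coefficient-row table.

## 7. What the synthetic tests do and do not show

The generator emulates the *structure* of continental trapping data —
bout/grid effort heterogeneity, recaptures, missing site-years, spatially
correlated climate with a sign-flipping mode, the lagged
mast-to-consumer chain.  It does not emulate demography (survival,
stage structure), dispersal, species interactions, observation covariates
(moon phase, weather on trap nights), non-stationary climate trends, or
realistic (weaker, noisier) effect sizes.  Passing recovery tests shows
the estimators can detect a dipole of the modeled form at the documented
signal strength; it does not certify power or calibration on real NEON
data.

Problem sizes used by the test suite and the acceptance script: the
default 23-site, 10-analysis-year world (~1.3 M trap-night rows) for
end-to-end runs, with 20 replicate worlds for the dipole-recovery and
null-world experiments, 400 null replicates (15 labels, 200 permutations)
for the MRM type-I check, and 500 runs × 1000 resamples for bootstrap
coverage.

## 8. Known limitations

- Bootstrap and permutation inference ignore pair dependence beyond what
  the response-permutation null captures; the block bootstrap is a
  sensitivity option, not a default.
- The low-capture rule's wording is ambiguous ("maximum of one individual
  for at least 2 years"); the implemented reading (never exceeds the
  threshold) is configurable.
- Whether month-qualification should apply to every year or only the best
  year is ambiguous; per-year is implemented.
- `derive_annual` assumes the monthly table carries one row per
  (site, year, month); duplicate rows are not detected.
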