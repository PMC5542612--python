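# Methods

This note documents the model behind `areadep`, the defaults it ships, the
numerical conventions it fixes, and what its synthetic test bed does and
does not establish about real data.

## The composite-index model

The package operationalizes the standard multiple-deprivation framework:
deprivation is not a single quantity but a combination of more specific,
separately measurable forms, each represented by a *domain* of indicators
and combined with explicit weights. The pipeline is rank-based throughout —
every comparison between areas is ordinal — which makes it robust to the
heavy right tails typical of small-area administrative rates, at the cost
of discarding interval information.

### Indicator construction

Four indicator kinds cover the default 28-input set: count rates
(numerator/denominator, optionally per 1,000), per-capita dollar amounts,
indirectly standardized event ratios (observed deaths over the expectation
under reference age-band rates — an SMR), and mean distance from the area
centroid to the nearest three facilities of a category. Nearest-*three*
rather than nearest-one reflects that the closest facility is not always
the one used. Distances are planar Euclidean on projected coordinates; road
or network distances would be more faithful in rugged terrain but require a
network dataset, so the metric is kept pluggable. All indicators are
oriented so larger = more deprived before any ranking.

Zero denominators (an area with no school leavers, say) set the indicator
to 0 with a logged warning rather than raising: a zero eligible population
carries no evidence of deprivation on that indicator, and tiny special-case
areas must not crash a national run. The alternative policy (`exclude`) is
available where dropping such areas is preferred.

### Domain recipes

- *Sum-rate* (Employment, Income, Crime): indicators share a denominator,
  so their rates are summed — algebraically identical to pooling numerators
  and dividing once. Ranks from a sum-rate domain are invariant to any
  strictly increasing rescaling of the score.
- *Min-max weighted* (Housing): the two census housing rates are scaled to
  [0, 1] and combined 60/40 (overcrowding above renting, consistent with the
  deprivation literature). Factor analysis is unsound on two items, which is
  why this domain uses fixed weights; the normalization choice is checked by
  the sensitivity analysis described below.
- *FA-weighted* (Health, Education, Access): each indicator is ranked with
  mean ties and transformed to normal scores using the Blom plotting
  position (constants 3/8, 1/4), which bounds the influence of outliers;
  the weighted sum uses either frozen published-profile weights
  (`nz2013`) or weights re-estimated from the data (`estimate`).

Weight estimation fits a single-factor maximum-likelihood factor model on
the standardized score matrix (equivalently, its correlation matrix) and
takes regression-method scoring coefficients, which for one factor are
proportional to loadingᵢ/uniquenessᵢ by the Sherman–Morrison identity;
they are normalized to sum to 1. One factor admits no rotation, so the fit
is identified up to sign; the factor is oriented so summed loadings are
positive. A negative normalized coefficient is *warned about, never
clipped* — with correctly oriented deprivation indicators all weights
should be positive, so a sign flip almost always means mis-oriented input.
The ML fit is scikit-learn's EM-based `FactorAnalysis`; it reproduces
R's `factanal` on the same data to four decimals.

The shipped `nz2013` profile freezes the published weight tables
(Health 0.04/0.08/0.19/0.28/0.42; Education 0.06/0.13/0.25/0.26/0.30;
Access 0.15/0.15/0.20/0.23/0.26). Printed weights are rounded to two
decimals and can sum to 0.99–1.01; they are accepted with that slack and
renormalized exactly when applied, preserving the printed ratios.

### Exponential transform and combination

Domain ranks enter the index through X(R) = −k·ln(1 − R(1 − e^(−top/k)))
with scaled rank R = rank/n. X(1) = top holds for every k, so k is pinned
by the second anchor, X(1 − p) = mid. For the default (top, mid, p) =
(100, 50, 0.10) the substitution u = e^(−mid/k) reduces the anchor to the
quadratic (1−p)u² − u + p = 0, giving u = p/(1−p) and k = 50/ln 9 ≈
22.7560; generic anchors are solved by bracketed root-finding to 1e-12. We
solve rather than hard-code so the tail property (10% of areas above 50)
holds *by construction* for any anchor setting; the calibrated k is
reported in run metadata. Anchors with mid ≥ top·(1−p), or p ≥ 0.5 in the
symmetric case, admit no constant and raise a calibration error.

Domain weights default to Income/Employment 28% each, Health/Education 14%,
Housing 9%, Crime 5%, Access 2% — Access weighted least because proximity
to services associates with rurality rather than with deprivation. For
leave-one-out variants ("index without Income", etc.) the excluded domain's
weight is redistributed proportionally across the remainder. No reweighting
rule for exclusion variants is canonical; proportional renormalization is
the minimal-assumption choice and is recorded in output metadata.

Quantile classification is equal-count over areas (group g covers ranks in
(n(g−1)/k, ng/k]), not population-weighted, because the classification is
of area ranks. Only quintiles and deciles are accepted by default.

No shrinkage is applied to small-area estimates anywhere in the pipeline:
shrinking toward regional or national means can mask exactly the small
pockets of deprivation the index exists to find.

### Validation battery

`validation` computes: (i) the full Spearman matrix over the index rank,
all domain ranks and mean-tie-ranked outcome rates, with t-approximation
p-values at n ≥ 20 and permutation p-values below that; (ii) the percentage
of flagged (e.g. rural) areas per decile of any ranking; (iii) per-parent
five-number summaries of ranks ordered by median (boxplot statistics, with
linear-interpolation quartiles fixed as the convention); and (iv) the
housing-normalization sensitivity check, rebuilding the housing domain
under min-max, Blom and raw-rank normalization and correlating the
resulting rankings pairwise.

## The synthetic generator

The generator emulates the study conditions the pipeline targets: 5,958
areas with mean population 712 on bounds 501–999 (populations are scaled
beta draws targeting that mean — integer-uniform draws on those bounds
would average 750), age-band shares from a Dirichlet around a realistic
national profile with the working-age denominator equal to the 15–64 band
total (a stochastic 60–70% share), a 15% rural fraction, and 20 parent
regions with N(0, 0.25²) region-level deprivation shifts.

A single latent factor L ~ N(0, 1) drives all non-access numerators:
count indicators are Binomial(denominator, logistic(α + λ·L + domain-shared
noise + indicator noise)) with per-indicator base rates α chosen at
realistic prevalences, income amounts are log-normal with location
increasing in the latent signal, and deaths are Poisson around the age-band
expectation scaled by exp of the signal. Loadings λ (0.35–0.85) follow the
published weight orderings within each domain; they are calibration
choices, since indicator-level distributions are not published. The
domain-shared noise component (sd 0.35) gives each domain its own
correlated residual, which is what makes factor-analysis weighting and
domain-correlation patterns meaningful rather than degenerate. Rural areas
get a −0.3 latent shift, producing the documented pattern in which the
rural share declines across deprivation deciles and access deprivation
correlates *negatively* with the index. Outcome rates invert the Gaussian
rank-correlation identity ρ_s = (6/π)·arcsin(r/2) so their Spearman
correlation with L hits the 0.8 target before a monotone logistic mapping.

Facilities are placed 80% near random urban centroids (2 km jitter) and
20% anywhere, at a density of max(5 × parents, 2.5% of areas) per category
— density must scale with region count or small simulations leave whole
urban clusters artificially remote. The legacy-geography crosswalk maps
~6.3 legacy units per area, of which 2.21% straddle two or three areas
with population-proportional shares.

All randomness flows from one master seed through named sub-streams
(CRC-32 of the component name spawns each generator), so adding a new
component never perturbs existing draws and identical configs are
bit-reproducible.

### What the synthetic tests do and do not show

Passing tests establish that the machinery is correct: ranks, transforms,
weights and reports do what the formulas say, and when data truly follow a
one-factor structure the pipeline recovers it (index–latent Spearman ≈ 0.95
at full scale). They do not establish substantive results about any real
country: real deprivation is not exactly one-dimensional, real indicator
noise is not exchangeable-binomial, spatial autocorrelation beyond the
parent-region shifts is absent, and the generator's loadings are choices,
not estimates. Published headline correlations from restricted
administrative data (e.g. index–smoking ≈ 0.8) are emulated in structure,
not reproduced in value.

## Numerical conventions and degenerate inputs

- One tie rule everywhere: mean of tied positional ranks (scipy `average`),
  for indicators, domains, the index, and ranked outcomes.
- Min-max normalization of a constant column raises (every area tied — a
  degenerate scale, not a computable one).
- An SMR with observed events but zero expected events raises; zero
  observed with zero expected is 0.
- Spearman correlation requires n ≥ 3 and non-constant inputs; the
  two-area sensitivity comparison falls back to exact monotone agreement.
- Apportioned counts stay fractional; rates are computed after summation.
- Quartiles in five-number summaries use linear interpolation.
- Problem sizes in the test suite: unit tests run on a 1,200-area bundle;
  the end-to-end recovery, factor-weight recovery and sensitivity checks
  run ten full 5,958-area replicates, which keeps the whole suite in a few
  minutes.

## Known limitations

- No spatial boundary polygons; geography is centroids plus a share-based
  crosswalk, and crosswalk shares are inputs, never computed from geometry.
- Access distances are straight-line, not road-network.
- No seasonal adjustment of benefit counts; no multi-factor or rotated
  weighting models; no population-weighted quantiles.
- The factor-weight estimator assumes a dominant single factor; on data
  with two comparable factors the single-factor weights are not meaningful
  (the negative-coefficient warning is the first symptom).
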