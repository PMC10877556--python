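# Methods

## The model

The pipeline links gridded tetrapod species richness to two climate drivers
— contemporary climate and climate instability — directly and through
community-wide traits.  All relationships are estimated with a piecewise
structural equation model (pSEM): a set of local OLS regressions over a
directed acyclic path model, rather than a single covariance-matrix
likelihood.  The theoretical DAG is

```
climate ──────────────┐
   │  ╲               ▼
   │   ├─► body_size ─────────┐
   │   ├─► size_variance ─────┤──► richness
   │   └─► trophic_structure ─┘      ▲
instability ─────────────────────────┘
```

with both climate drivers feeding every trait and richness, every trait
feeding richness, and free (correlated) residual covariances among the three
traits.  Each endogenous node gets one OLS submodel.  Standardized
coefficients are `b · sd(x)/sd(y)`; for a single-predictor submodel this
equals the Pearson correlation exactly.

**Effects on richness** are decomposed per predictor into a direct effect
(the edge coefficient into richness), an indirect effect (the sum over all
mediated paths of the product of standardized coefficients along each path)
and the total effect, defined as their sum.  The decomposition is a graph
computation over the fitted coefficients, so `total = direct + indirect`
holds exactly by construction.

**Global fit** is assessed by tests of directed separation.  The basis set
contains one conditional-independence claim per non-adjacent node pair,
conditioning on the union of both nodes' parents; the node later in
topological order is the regressed variable and the claim is tested by the
t-test p-value of the added predictor.  Fisher's C = −2·Σ ln pᵢ is referred
to a chi-square distribution with 2k degrees of freedom.  Two pair classes
are excluded from the basis set: declared correlated-error pairs (free
covariances) and pairs of two exogenous nodes, whose joint distribution the
model does not constrain.  A model with an empty basis set is reported as
saturated, with C undefined and df = 0 — the full theoretical DAG above is
saturated in this sense, which is expected and not an error.

**Composite nodes.** In the full pipeline the richness submodel uses three
composites: contemporary climate (temperature Bio1 + precipitation Bio12),
climate instability (the two Last Glacial Maximum anomalies), and
community-wide traits (the three trait variables).  A composite is the
coefficient-weighted sum of its z-scored indicators, the weights taken from
an OLS of the (unscaled) response on the indicators; scores are re-
standardized to unit variance and treated as fixed regressors downstream
(two-step estimation).  Because re-standardization absorbs any common factor
in the weights, z-scoring the response would change nothing downstream; we
keep the response on its own scale so that, on exactly standardized
noiseless data, the weights equal the generating coefficients.  For effect
decomposition, a deterministic edge from each trait into the trait composite
carries coefficient `w_t / sd(raw score)`, which routes
climate → trait → composite → richness paths correctly.  Claims pairing an
indicator with its own composite, or an indicator with the composite's
response, are excluded from the basis set — the composite constraint makes
them untestable rather than informative.  This convention for composites in
d-separation was genuinely open; we fixed it as above and it is asserted by
the tests.

## Spatial filtering

Residual spatial autocorrelation is absorbed with distance-based Moran's
eigenvector maps (dbMEM).  From the retained cell centroids we build a
minimum spanning tree; the truncation distance `t` is its longest edge
(guaranteeing a connected graph), and spatial weights are
`w_ij = 1 − (d_ij/(4t))²` for `0 < d_ij ≤ t`, zero otherwise.  Eigenvectors
of the doubly centered weight matrix `H W H` with positive eigenvalues form
the MEM basis; each is zero-sum and unit-norm, and its Moran's I equals
`(n/S₀)·λ`, so Moran's I is non-increasing with rank.

Eigenvectors enter each submodel by **MIR forward selection** (minimization
of residual Moran's I): starting from the non-spatial residuals, the
candidate eigenvector whose inclusion (with a full refit) most reduces
|Moran's I| of the residuals is added, until a permutation test no longer
rejects spatial independence at α = 0.05, no candidate reduces |I|, or the
basis is exhausted.  Ties break toward the lowest eigenvector rank.  An
alternative stopping rule — an absolute ceiling on |I| (default 0.8 where
enabled) — is exposed in the configuration because the study tradition also
reports such a threshold; it is off by default, and we deliberately take no
position on whether a ceiling of 0.8 or 0.08 was intended in that
tradition.  Moran permutation p-values are
`(1 + #{|I_perm| ≥ |I|}) / (n_perm + 1)` with 999 permutations by default
and a mandatory seed in pipeline mode.

A note on a classic smoke test: on a regular 1-D transect the leading MEMs
approximate cosines of increasing frequency.  Under the MST-truncated
construction above, the approximation is dominant but not tight — MEM₁
correlates |r| ≈ 0.88 with the half-cosine at n = 30 (identical to three
decimals under the PCoA-based PCNM construction), with the remainder loading
on the third harmonic.  The correlation exceeds 0.95 only when the
connectivity radius is several times the nearest-neighbor spacing, which the
MST rule on a regular transect never produces.

## Data preparation

*Gridding.*  The analysis grid tiles a projected extent with square cells
(canonically 2° on a Mollweide equal-area projection, ~220 km).  A species
is present in a cell iff any component of its (multi)polygon covers the cell
*center*; boundary contact counts as presence (deterministic tie-break).
Cell-overlap membership is deliberately not used.  Invalid polygons are
repaired (`make_valid`) or skipped with a log entry.  Cells with fewer than
3 species in a group are excluded from that group's analysis; an
intersection mode (cells adequate for every group at once) is available.

*Traits.*  Trophic levels from diet composition: strictly more than 90%
plant-derived diet → primary consumer (weight 2), strictly more than 90%
animal-derived → secondary consumer (weight 3), otherwise omnivore (weight
2.5); the weights follow nitrogen-isotope positioning of omnivores midway
between the other levels.  The trophic-structure index is the mean weight of
the species present (2 = bottom-heavy, 3 = top-heavy).  Community body size
is log10 of the median body mass in grams; size variance is the sample
(n−1) variance of log10 mass.  Computing the variance on the log scale is a
design choice: raw-gram variance is dominated by the largest species, and
log mass is the scale on which the size distribution is approximately
symmetric; raw-scale variance remains available via a flag.  Single-species
cells get variance 0 (they are excluded by the richness filter anyway).

*Climate.*  Rasters are sampled at cell centroids by nearest-cell lookup
(mirroring centroid extraction rather than cell-mean aggregation; source
rasters are typically much finer than the analysis grid).  Anomalies are
signed differences, current − LGM, zero meaning no change; an absolute-value
mode exists because "higher anomaly" language in the literature often means
magnitude.  The signed mode is the default and is what the synthetic
validation uses.

*Collinearity prefilter.*  Before model fitting, any predictor pair with
|Pearson r| > 0.7 is reduced by dropping the member whose single-predictor
model for the relevant response has the higher AIC, iterating until no pair
exceeds the threshold; decisions are logged.

## The synthetic generator

The generator emulates the study design so every stage is testable without
external downloads.

- **Climate fields** are kernel-smoothed white noise (Gaussian filter,
  bandwidth = `spatial_range`, default 3 cells) plus a latitudinal gradient
  peaking at the equator; LGM fields subtract a further independent
  autocorrelated perturbation (≈4 °C cooling, ≈150 mm drying on average), so
  anomalies vary in space.
- **Ranges** are discs centered at climate-dependent locations (cells near a
  species' thermal optimum are likelier centers) with random radii between
  1.5 cells and a third of the domain.
- **Traits**: log-normal body masses (log10-mass SD 0.4) whose means track
  local temperature downward for birds and mammals and upward for squamates
  and amphibians; diet mixtures giving omnivore-leaning endotherm pools and
  secondary-consumer-leaning ectotherm pools, so all three trophic classes
  occur.
- **Structural table**: variables generated in topological order from the
  DAG above; each endogenous variable is the coefficient-weighted sum of its
  parents plus Gaussian noise.  Residual SDs are derived from the
  DAG-implied covariance so every node has unit population variance, making
  the generating coefficients standardized and directly recoverable; an
  explicit `noise_sd` overrides this (needed, e.g., for noiseless-chain
  checks).  Trait residuals are pairwise correlated (ρ = 0.3 by default)
  through a joint Cholesky draw, mirroring the free trait covariances in
  the model.  Default coefficients are moderate (|β| between 0.15 and 0.45)
  with the signs the study system predicts: positive climate effects on
  richness, negative body-size and trophic-top-heaviness effects.  Richness
  is generated as a continuous standardized variable, matching the OLS
  treatment of richness in the models; `richness_to_counts` exponentiates
  and rounds for gridding-stage exercises only.
- In *spatial* mode the exogenous variables are standardized smoothed
  fields and half of each residual SD is spatially structured, giving MEM
  selection something real to absorb; in the default i.i.d. mode all
  sources are white, the cleanest setting for coefficient recovery.
- One global seed feeds three independent substreams (fields, structural
  table, species), so stages can be regenerated in isolation.

What the generator does **not** emulate: realistic range shapes or
dispersal, phylogenetic trait correlation, observation error in trait
databases, coastlines/land masks, and any coupling between the rasterized
richness and the structural table's latent richness.  Passing tests
therefore demonstrate that the statistical machinery is correct and
calibrated under the stated generating process, not that the empirical
global results are reproduced — the latter require the original range
polygons, trait databases and climate rasters.

## Problem sizes and numerical choices

Validation runs use 2000 cells (50×40) for coefficient recovery (100 seeds
for the bias summary), 500 simulations of n = 300 for Fisher's C
calibration, and 1000 replicates with 999 permutations each for the Moran
permutation test's type-I error — sizes at which Monte Carlo error is well
inside the asserted tolerances.  Eigen-decompositions use symmetric
`eigh` with a relative positive-eigenvalue cutoff of 1e-9; rank deficiency
in any design matrix raises an error naming the offending columns; constant
variables are rejected wherever a statistic would be undefined (Moran's I,
composite indicators).  Forward selection improvements must exceed 1e-15 to
count, which makes selection deterministic under ties.

## Known limitations

- OLS on (latent continuous) richness, not a count likelihood; a count GLM
  is a possible future hook and is off by default.
- Negative-autocorrelation MEMs are never candidates for selection.
- Claims in the d-separation test are tested by OLS t-tests including each
  submodel's selected MEMs; dependence among claims sharing data is ignored,
  as is standard for Fisher's C.
- The full synthetic route (ranges → aggregation → composites → pSEM)
  carries qualitative ground truth only; exact recovery checks run on the
  structural table where coefficients are known.
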