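# Methods

## Survey model and sub-metric reduction

A site is described by its Available Intertidal Habitat (AIH, hectares) and
a set of mapped algal patches; quadrats (default 0.25 m²) carry percentage
cover, wet biomass (g m⁻²) and an entrainment flag.  Patch membership of a
quadrat is an explicit input (patches are mapped in the field), never
inferred from a cover threshold.  Quadrat cover may be any real value in
[0, 100]; the 5×5 grid used in the field is a measurement aid, not a
quantisation of the data model.

The reductions are:

* **AA** = Σ patch areas; **AA/AIH %** = 100·AA/AIH.
* **% cover of AIH** = 100 · Σ_patches(area × mean fractional cover of that
  patch's quadrats) / AIH.  A patch with positive area but no quadrats is a
  protocol violation and raises (at least one transect per patch is
  required); quadrat means are pooled directly per patch, without an
  intermediate per-transect average (a transect-weighted variant would be a
  one-line change in the patch mean).
* **biomass over AA** = arithmetic quadrat mean, since quadrats are placed
  only inside patches.
* **biomass over AIH** = biomass_AA × AA/AIH.  The habitat outside mapped
  patches is treated as bare.  This dilution convention is the package's
  choice: biomass is only ever measured inside patches, so the AIH-wide mean
  must be a model statement, and "zero outside patches" is the conservative
  one.
* **% entrained** = share of quadrats with the entrainment flag set.

Total bloom biomass (tonnes wet) = cover (ha) × 10⁴ × mean biomass
(g m⁻²) × 10⁻⁶, and is bilinear in its two inputs.

## EQR scoring and classification

Each sub-metric is scored by piecewise-linear interpolation through six
anchors fixed at EQR 1.0, 0.8, 0.6, 0.4, 0.2, 0.0.  The interpolant is
continuous and non-increasing; values above the upper-limit anchor clamp to
EQR 0.  Of the two affected-area criteria (AA in ha; AA as % of AIH) only
one enters the final average.  The default `lenient` rule takes the one with
the higher EQR — reading the "use the lower of the two criteria" instruction
as "the lesser indicated impact", which avoids double-penalising the same
pressure; the opposite `strict` reading is available as a switch because the
published text does not settle it.  Ties go to absolute AA.

The final EQR is the arithmetic mean of the contributing sub-metric EQRs.
Status bands are half-open with the boundary belonging to the upper class
(0.8 → High, 0.6 → Good, …); because the interpolant is continuous this
convention never changes an EQR value, only the label at exact boundaries.
A screening rule flags sites whose AA/AIH strictly exceeds 5 % as requiring
a full survey; a survey with mapped patches but no quadrats is scored from
the affected-area criteria alone and marked `screening_only`.  Rounding (2
decimals for reported EQRs, whole euro for costs) happens only in the
reporting layer.

## Metal statistics

* **Spearman ρ** is computed from average ranks (ties share the mean of
  their spanned ranks) followed by a Pearson correlation of the rank
  vectors — the tie-corrected form.  p-values default to the two-sided t
  approximation on n−2 df; an exact enumeration over all n! permutations is
  available for n ≤ 10 (relevant at n = 8 sites) and a Monte-Carlo variant
  beyond that.
* **Fisher-z averaging**: r̄ = tanh(mean atanh r) with a normal-theory CI
  (±1.96·sd(z)/√n) formed on the z scale and back-transformed.  The CI
  convention is the package's own; published CIs computed by unstated
  methods are not reproduced digit-for-digit.
* **Metal Content Index** = geometric mean of a sample's concentrations;
  requires strictly positive values.
* **Normalisation** is per-variable z-scoring with the n−1 denominator;
  all multivariate analyses run on Euclidean distances of the normalised
  data.
* **Nested PERMANOVA** partitions SS_total = Σ_{i<j} d²_ij / N into a
  status term, a site-within-status term and a residual via the standard
  distance-based identity (within-group pair sums divided by group size).
  Pseudo-F(status) = MS_status/MS_site — sites are the replicates of
  status — and pseudo-F(site) = MS_site/MS_residual.  Significance for the
  status term permutes intact site units across status labels (preserving
  the number of sites per class); the site term permutes samples across
  sites within each status class, the exchangeable units under that null.
  With 8 sites the status permutation distribution is coarse (560 distinct
  arrangements for a 3/3/2 design), so an F-distribution approximation is
  reported alongside; a Monte-Carlo p-value in the PRIMER sense (sampling
  the asymptotic chi-square mixture) is not implemented.  Unbalanced
  designs use sequential SS with status before site, the natural ordering
  of a nested hierarchy.  A single status class degenerates cleanly to a
  one-way layout in which the site pseudo-F equals the classical ANOVA F
  on univariate Euclidean data (verified to 1e-9 in tests).
* **PERMDISP** computes each sample's distance to its group centroid in the
  original coordinate space (equivalent to the distance-based formulation
  for Euclidean distances), takes the one-way ANOVA F on those distances,
  and obtains overall and pairwise p-values by permuting group labels.
* **PCA** eigendecomposes the correlation matrix; percent variance is the
  eigenvalue share of the trace and scores project the z-scored data onto
  the loading vectors.  Each loading vector's largest-magnitude element is
  made positive so output is deterministic across eigensolvers.
* **Per-metal one-way ANOVA** across sites is followed by pairwise
  permutation tests on the difference of means, compressed to a compact
  letter display by the insert-and-absorb algorithm (groups share a letter
  iff not significantly different).

All stochastic routines take an explicit seed and default to 9999
permutations.

## Management arithmetic

Dry weight = wet × (1 − moisture), default moisture 0.796.  Note that one
published dry-weight figure (160 t from 540.19 t wet) is inconsistent with
this formula (it yields 110.20 t); the formula is followed as stated and no
attempt is made to match that figure.  Metal load (kg) = dry tonnes × 10³ ×
mg kg⁻¹ × 10⁻⁶.  Disposal costs use €260 per wet tonne (landfill) and €16
(arable land), rounded half-away-from-zero to whole euro.  Regulatory limits
are encoded with explicit jurisdiction/commodity/metal entries; limits that
apply only to the inorganic species (e.g. inorganic As) are flagged as not
directly comparable to total concentrations rather than silently compared.
Ranged published limits are split into explicit entries where the commodity
split is known, otherwise the strictest bound is encoded and noted.  CRM
recovery passes when |found − reported| ≤ k·√(u_found² + u_reported²),
k = 2 by default.

## Synthetic data

The survey generator draws sub-metric EQR targets uniformly inside the
target status band (15 % margin from each edge), inverts the boundary table
to metric values, and realises them with sampling noise: fractional cover
per quadrat ~ Beta with mean c and concentration 150, biomass ~ lognormal
with σ = 0.2 and mean matched to the target, entrainment ~ Bernoulli.
Patch areas split the affected area by a Dirichlet(5) draw; by default two
transects of 12 quadrats are placed per patch (protocol minimum 10 per
transect).  When the AIH is not fixed by the scenario it is derived so the
absolute and relative affected-area criteria score identically.

Because biomass over the AIH is tied to biomass over the AA by the dilution
AA/AIH, not every sub-metric can sit inside the target band simultaneously
(for Moderate, biomass values must lie in (500, 1000] g m⁻² while
AA/AIH < 50 %, forcing the AIH-diluted value below 500).  The generator
therefore solves the entrainment target last so the *expected final EQR*
sits at the centre of the target band — the quantity classification
actually depends on.  With these noise settings the expected-to-observed
EQR error is an order of magnitude smaller than the half-band width, and
200 scenarios across all five classes classify to target without misses in
the test suite.

The metal generator draws concentrations lognormally around per-site
medians (defaulting to the bundled site-mean table) with a status-dependent
coefficient of variation (High 0.10, Good 0.20, Poor 0.30, Moderate 0.50,
Bad 0.60), emulating the empirical pattern that degraded sites show wider
multivariate dispersion, with Moderate the widest.  What the generators do
*not* emulate: spatial autocorrelation within patches, transect-level
clustering, seasonal dynamics, correlated metal–metal noise within samples,
and detection limits/censoring.  Tests passing on synthetic data therefore
validate the arithmetic and the statistical machinery, not the field
behaviour of real blooms.

## Known limitations and fixed conventions

* The published Mo–EQR Spearman coefficient cannot be recovered from the
  published 2-decimal site means: rounding creates a tie between two sites
  that the underlying data evidently did not have (breaking the tie
  reproduces the published value exactly).  The corresponding regression
  test documents this and is expected to fail on the Mo row only.
* Published per-sample concentrations were never deposited, so the
  multivariate tables (mean squares, pseudo-F, dispersions, PCA variance
  shares) are validated by property-based tests — classical-ANOVA
  equivalence, exact SS conservation, type-I-error calibration of the
  status test (500 null simulations, 199 permutations), planted-dispersion
  recovery — rather than by value reproduction.
* Simulation sizes in the test suite (8 sites × 5–20 samples, 199–999
  permutations) are chosen so the full suite runs in well under a minute of
  statistical computation while keeping binomial error bounds tight enough
  to be meaningful.
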