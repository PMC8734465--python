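# Methods

This note documents the statistical models, estimators and design
choices behind `standpp`, in the spirit of a model/methods appendix: what
is computed, under which assumptions, with which defaults, and what the
synthetic test-bed does and does not establish about real censuses.

## Census model

A census is a table of uniquely tagged stems with plot-level metric
coordinates (origin at the southwest corner), a species code, dbh (cm at
1.3 m, stored to 0.1 cm as measured), a live/dead status, and an
individual identifier shared by the stems of one multi-stemmed plant.
Census inclusion thresholds follow standard forest-dynamics-plot
protocol: live stems ≥ 1 cm dbh, standing dead stems ≥ 5 cm dbh.
Validation reports violations (duplicate tags, out-of-window
coordinates, sub-threshold diameters, unknown status values, individuals
spanning species) rather than raising, so a census can be triaged in one
pass.

Quadrat and raster cells are half-open `[a, a+s) × [b, b+s)`, with the
plot's maximal edges folded into the last cell.  This makes cell
assignment a true partition (no stem counted twice, none dropped) and is
applied identically by quadrat assignment and raster sampling.  Field
protocols do not usually state how digitised stems landing exactly on a
quadrat boundary were resolved; the half-open rule is this package's
convention and is documented rather than inferred.

## Stand summaries

Density counts **individuals** (multi-stemmed plants collapse to one),
while basal area `π(dbh/200)²` and allometric biomass sum over **all
qualifying stems** — the standard convention for shrubby, coppiced or
sprout-origin stems.  Biomass equations are data, not code: a CSV of
per-species coefficients in either the `a·dbh^b` or
`exp(a + b·ln dbh)` parameterisation (mathematically interchangeable),
with a wildcard fallback row.  The shipped generic default
(`a = 0.12, b = 2.4`, kg from cm) is a placeholder of plausible
temperate-tree magnitude and is expected to be replaced by the user's
species-specific table.  Biomass for multi-stemmed individuals is summed
per stem, mirroring the basal-area rule.

Diameter histograms default to 5-cm classes from the 1-cm census
threshold (left-closed bins, last bin closed).  The qualitative
"reverse-J" label is operationalised reproducibly: a histogram is
reverse-J iff its counts are non-increasing across all bins; unimodal
iff counts rise to a single interior mode and then fall; otherwise
"other".

## Spatial statistics

All three second-order statistics use an Epanechnikov kernel
`k_h(u) = 0.75 (1 − (u/h)²)/h` in pair distance, bandwidth default
`h = 5` m.  Default lag grids: 1–50 m for the pair-correlation function
and 1–150 m for the mark statistics, both configurable; lags beyond half
the shorter window side are refused unless explicitly overridden.

**Pair-correlation function.**
`ĝ(r) = Σ_{i≠j} k_h(r − d_ij) w_ij / (λ̂² |W| 2πr)` with intensity
`λ̂ = n/|W|` and translation edge weights
`w_ij = |W| / ((W_x − |dx|)(W_y − |dy|))`, exact for rectangular
windows.  Two numerical caveats are documented deliberately:

* *Small lags.* For `r < h` the kernel window is truncated at zero
  distance while the estimator still divides by `2πr`, which biases the
  curve upward near the origin.  Curves should be interpreted for
  `r ≥ h`; the closed-form verification below therefore evaluates lags
  from 6 m up.
* *Cluster processes with estimated intensity.* Normalising by the
  observed `n²` makes `ĝ` slightly biased for strongly clustered
  patterns when the expected number of clusters in the window is small
  (the same replicate that has few clusters has both fewer points and a
  proportionally more clumped pattern).  The effect vanishes as the
  point count per window grows; the Thomas-process verification uses a
  parameterisation with a large expected count (~7,000 points) where the
  estimator and the analytic pair-correlation function agree within
  Monte Carlo error at every lag.

**Mark-correlation function.**
`kmm(r)` is the kernel-weighted mean of `m_i m_j` over r-separated pairs
divided by `μ²` (the squared mean mark).  It is a ratio estimator, so
edge effects largely cancel and no explicit correction is applied; it is
exactly invariant to rescaling all marks by a positive constant.  Values
below 1 mean trees near conspecifics are smaller than expected —
the crowding signature.

**Schlather's Moran's-I bivariate mark correlation.**
`I(r)` is the kernel-weighted mean over cross pairs (focal i, other j)
of `(m1_i − μ1)(m2_j − μ2)/(σ1 σ2)`, with marginal moments (population
sd).  It lies in [−1, 1] up to estimation noise, is invariant to
positive affine transforms of either mark set and flips sign under
negative ones.  When both arguments are the same pattern, self-pairs are
excluded.

Lags whose kernel support contains no pair return 0 with a logged
warning rather than NaN, so envelope machinery downstream stays total.
All estimators are checked against direct O(n²) brute-force oracles (no
spatial indexing, plain kernel sums) to 10⁻¹⁰ on 400–500-point
instances.

Spatial analysis uses one point per individual, marked with the largest
stem's dbh (configurable to per-stem).

## Monte Carlo envelopes

Null models: complete spatial randomness conditioned on the observed
point count (the clustering null for `g`), and random labelling — marks
permuted over all trees (`kmm`) or over the non-focal pattern only
(`I`), with point coordinates fixed and the mark multiset preserved
exactly.  Statistic/null pairings are enforced; mismatches are
configuration errors.

With `nsim` replicates and envelope rank `k`, the per-lag bounds are the
k-th smallest and k-th largest simulated values; under the null the
observed value falls outside with probability exactly `2k/(nsim+1)`
pointwise (0.05 for the default 199 simulations, k = 5, matching the
conventional "95 % envelope" reading).  Envelopes are **pointwise**:
read across many lags they are liberal as a global test.  This matches
how such figures are conventionally read per lag; a rank-corrected
global envelope is noted as future work.  Calibration is verified by
simulation: patterns drawn from the null are called outside the envelope
at a rate statistically indistinguishable from the nominal level (150
calibration runs of the full 199-simulation test).

Replicate randomness uses per-replicate `SeedSequence` substreams from
one master seed, so replicate i is identical whatever `nsim` or the
thread count, and a fixed seed reproduces envelope CSVs byte-for-byte.

## Land-use covariates and variable importance

Predictors per tree: sampled categorical/continuous rasters (ESRI ASCII
grids), the species' focal-window abundance surface (counts per 20-m
cell smoothed by a 3×3 moving mean, truncated at plot edges — corner
cells average over their 4 existing neighbours), and five neighbourhood
features over all trees within 10 m (count; mean and CV of dbh; mean and
CV of distance; CV = sample sd/mean, undefined below two neighbours).
Trees closer than the radius to a plot edge keep a border flag rather
than being dropped; exclusion is a switch.

The tree learner re-derives the conditional-inference recipe rather than
wrapping an external implementation: at each node every predictor is
tested for association with the response — a standardised cross-product
(correlation-type) statistic with a normal approximation for continuous
predictors, a one-way mean-contrast quadratic statistic with a
chi-square approximation for categorical ones — p-values are Bonferroni
corrected across predictors, and the node splits on the most significant
predictor (ties to the lowest column index) at its variance-reduction
maximising cutpoint.  Splitting stops when the smallest corrected
p-value exceeds `alpha` (default 0.05), the node has fewer than
`min_node` rows (default 20), or no cut leaves `min_leaf` (7) rows per
child.  Categorical predictors split on level subsets (exhaustive up to
8 levels, ordered-by-mean beyond).  This is an approximation of the full
conditional-inference framework (asymptotic rather than exact
conditional distributions), chosen for transparency; its type-I control
is verified empirically (pure-noise responses yield root-only trees in
≥ 95 % of runs at alpha = 0.05).

Importance is out-of-bag permutation importance: each of `n_iter`
(default 500) iterations fits a tree on a 63.2 % subsample and measures
the increase in held-out mean squared prediction error when each
predictor column is permuted; scores are averaged over iterations and
reported with per-iteration detail.  Scores are in response units
squared; rankings are invariant to affine rescaling of continuous
predictors.  In recovery tests the neighbourhood features are excluded
from the predictor set when asking whether the land-use mosaic is
recovered as the top driver, because a species' local abundance features
are mechanically collinear with the abundance response itself.

## Synthetic stands

The generator reproduces the statistical features the analysis assumes,
with ground truth retained for recovery tests:

* **Clustering:** per-species Thomas processes (parents Poisson with
  intensity ρ on the window buffered by 4σ to avoid offspring edge
  deficit; Poisson(μ_off) offspring displaced by isotropic Gaussian σ).
  The closed-form pcf gives an analytic acceptance surface.
* **Habitat structure:** a categorical land-use mosaic (Voronoi patches
  of uniform seeds on a 20-m cell grid, classes such as field-
  abandonment cohorts and woodlot) thins each species by per-class
  affinity weights — strong habitat-tied clustering, and zero-affinity
  classes hold no stems.
* **Marks:** lognormal dbh (right-skewed; reverse-J after binning), with
  optional crowding marks `exp(β0 − β·count_R + ε)` (locally negatively
  autocorrelated, `kmm < 1` at short lags) and gradient marks for
  bivariate scenarios.  Generated dbh is rounded to 0.1 cm and floored
  at the 1-cm census threshold.
* **Census plumbing:** ~5 % of individuals carry a second, smaller stem
  (exercising the individuals-vs-stems distinction) and ~5 % of stems
  ≥ 5 cm are flagged standing-dead.

The default configuration emulates a 35-ha (500 × 700 m) stand with
~10⁵ stems of 50 species on a geometric rank-abundance series tied to a
5-class mosaic.  Tests and the demo pipeline use smaller stem counts and
species numbers — the same generative structure at sizes chosen to keep
the suites fast — stated explicitly where used.

What the synthetic test-bed does **not** emulate: real species lists,
swamp hydrology and topographic covariates, dispersal interactions
between species, measurement error in mapping, and spatially varying
(inhomogeneous) intensity.  Passing recovery tests therefore show the
estimators and the importance machinery are correct and calibrated under
the stated generative models, not that any particular field pattern is
well described by a Thomas process.

## Determinism and numerics

Every stochastic component takes an explicit generator or seed;
pipelines derive all stage seeds from one master seed via
`SeedSequence`.  Rerunning a configuration reproduces every artifact
byte-for-byte (verified via SHA-256 manifests).  CSV floats are written
with `%.10g`; envelope and estimator code avoids NaN by contract
(empty-support lags return 0 with a warning).  Degenerate inputs are
errors where the mathematics is undefined (zero mean mark for `kmm`,
zero mark variance for `I`, fewer than 2 points for any pair statistic)
and reports where they are data problems (validation).

## Known limitations

* Pointwise envelopes only; no global rank envelope.
* Homogeneous nulls only; no inhomogeneous-intensity variants, no
  K/L-functions.
* The conditional-inference approximation uses asymptotic p-values, so
  its splits can differ from exact-conditional implementations on small
  nodes.
* The pair-correlation estimator is not bias-corrected below the
  bandwidth; interpret `r ≥ h`.
* Biomass defaults are placeholders; real analyses must supply their own
  allometry table.
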