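# Methods

This note documents the models, estimators and numerical choices behind
`vertexstats`, the assumptions each one makes, and what the synthetic
calibration suite does and does not demonstrate about real data.

## Surface templates

Cortical hemispheres are represented by closed triangle meshes; the
package's synthetic templates are recursively subdivided icosahedra
(`10·4^L + 2` vertices at level `L`, radius 100 mm, mean edge ≈ 3.8 mm at
level 5).  A level-5 pair totals 20,484 vertices and a level-6 pair
81,924, matching the vertex counts of the standard fsaverage5/fsaverage6
spherical templates; fsLR32k (64,984) and the hippocampal CIT168 space
(14,524) are carried as registry constants and can be backed by
user-supplied FreeSurfer or GIFTI geometry.  Subdivision keeps parent
vertices first and appends edge midpoints, so resolutions are *nested*:
down-sampling is an index restriction and is the exact inverse of
up-sampling on the nested block.  Hemispheres never share edges;
consequently clusters can never span the midline.  The hippocampal
synthetic stand-in is an open rectangular grid (unfolded-sheet topology),
since only the vertex count of the real template is fixed, not its
geometry.  The per-hemisphere split of the 14,524 CIT168 vertices is
assumed symmetric (7,262 each); nothing in the inference depends on it.

## Cohort matrix and container

The analysis currency is the N×V matrix (rows = subject or
subject-session, columns = left-then-right vertices).  Extraction
enumerates subjects lexicographically (a documented, platform-independent
choice), refuses subjects with a missing hemisphere, and stores sessions
as separate rows (long format) because the mixed model consumes long
data.  Medial-wall zeros are stored as-is; masking is an analysis-time
option.  The portable container is a single HDF5 file: float32 matrix
with gzip + byte-shuffle (the shuffle filter is what makes smooth float
data compress well), subject/session IDs, template tag, measure name and
an explicit format-version string checked on load.

## Smoothing

Surface smoothing is iterative neighbour averaging on the mesh graph:
each pass replaces a vertex value by the mean of itself and its
neighbours, per hemisphere.  The pass count matches the variance of the
requested Gaussian kernel, `n = ceil((FWHM²/(8 ln 2)) / edge²)`, minimum
1 — an approximation to a geodesic Gaussian kernel that needs only
adjacency.  The operator is linear, fixes constants, stays within the
input range, and preserves total mass up to the slight row-normalisation
asymmetry at the twelve degree-5 icosahedron corners (< 1% for a unit
spike in a degree-6 neighbourhood).  Because `n` is integer-rounded, the
realised smoothness overshoots slightly at small `n`; the residual
smoothness estimator (below) recovers a 10 mm request on the level-5 pair
to within the 7–13 mm band used in calibration.

## Vertex-wise models

**OLS.**  Design matrices are intercept-led; numeric covariates pass
through, categorical ones are dummy-coded (first level dropped), and rank
deficiency raises an error naming the dependent columns.  Rows with
missing covariates are dropped cohort-wide with a warning.  Vertices with
zero residual variance are flagged degenerate, carry t = 0 and are
excluded from cluster formation and resel area.

**Random-intercept mixed model.**  One grouping factor (typically subject
ID), one random intercept, one variance-ratio parameter
λ = σ_b²/σ_e² per vertex.  Because Z Zᵀ depends only on the grouping, a
single eigendecomposition whitens every vertex and every candidate λ;
REML is profiled over λ (σ_e² solved in closed form) and fixed effects
are GLS at the estimate.  Two estimators exist: a bounded scalar
optimizer (used by `fit_vertexwise_mixed`; matches `statsmodels` MixedLM
t-values to ~1e-6) and a vectorized grid search over {0} ∪ 81 log-spaced
ratios in [1e-4, 1e4] used inside permutation loops, where thousands of
refits must be cheap and, critically, *identical in form* between the
observed and permuted data.  Degrees of freedom are the deliberately
conservative N − rank(X) − (G − 1); corrected p-values may therefore
differ from softwares using Satterthwaite-style approximations.
Scaling is quadratic-to-cubic in N through the N×N eigendecomposition,
which is acceptable for the repeated-measures cohorts (tens to hundreds
of rows) this model targets.

## RFT cluster correction

Residual smoothness: each vertex's residual vector is normalised to unit
length; for every mesh edge the squared difference of normalised
residuals divided by squared edge length estimates the gradient variance
of the error field, and the pooled mean over unique edges converts to an
equivalent Gaussian FWHM via `FWHM = sqrt(4 ln 2 / mean)`.  (Pooled
per-edge averaging is used rather than triangle-area weighting; on the
near-uniform synthetic meshes the two agree, and the estimator is
validated by simulation: white noise estimates ≈ 1.18× the edge length,
as theory predicts.)  Resels are surface area over FWHM², excluding
degenerate vertices.

Cluster inference thresholds |t| at the two-sided forming threshold
(default p = 0.001, i.e. `t_c = t_isf(p/2, ν)`), splits suprathreshold
vertices by sign into mesh-connected components, and assigns each cluster
of k resels `P = 1 − exp(−E[m]·exp(−k·E[m]/E[A]))`, where `E[m]` is the
expected cluster count from the 2-D t-field EC density and `E[A]` the
expected suprathreshold area, both pooled over the two signs so the
corrected p controls FWER over both directions jointly.  The formulas are
the classical unified ones; their accuracy is established by simulation
(below), not by matching any particular implementation.  Nonstationary
(vertex-wise) smoothness is out of scope.

## TFCE permutation inference

The enhanced map is `TFCE(v) = Σ_h e_v(h)^E h^H dh` with E = 1, H = 2
(the recommended two-dimensional setting), positive and negative parts
enhanced independently on the hemisphere adjacency, output signed like t.
The integration grid is 100 equal steps from 0 to max|t| by default; the
top threshold is taken as exactly max|t| so the map is exactly
scale-equivariant (TFCE(c·t) = c³·TFCE(t)).  A vertex whose |t| falls
below the first step receives 0.  The engine is a union-find sweep over
descending thresholds (O(levels·V + E) per map) and matches an exhaustive
per-level component-labelling oracle to floating-point accuracy; the
single-isolated-vertex analytic limit h³/3 is met within 2% at
dh = h/100.

The null is the distribution of the per-permutation maximum |TFCE| under
row shuffling of the data matrix (the design stays fixed), with four
exchangeability schemes: all rows; within subject blocks; between equal
blocks moved rigidly; or within-then-between.  One pooled |max| null
covers both signs, controlling FWER jointly over directions.  Each
permutation draws its RNG substream from (seed, index), so results are
identical for any worker count.  Per-vertex corrected p is the exact
permutation p-value `(1 + #{null ≥ |TFCE_v|})/(1 + n_perm)`; the smallest
achievable value is `1/(1 + n_perm)` (100 permutations by default — use
more for p-values near 0.01).  Thresholding is decoupled from estimation
and never refits.

**Why permutations re-estimate the variance ratio.**  For the mixed
model, reusing the observed fit's per-vertex λ̂ inside permutations makes
the null anticonservative (measured family-wise error 0.29 at nominal
0.05 on a sessioned null): the observed maximum benefits from per-vertex
REML adaptation that mismatched permuted refits lack.  The default
therefore re-estimates λ per permutation with the grid REML, using the
same grid estimator for the observed map, which restores exactness
(measured 0.04).  Reuse remains available as `refit_variance=False` for
exploratory speed.  Row permutation (not Freedman–Lane residual
permutation) is the implemented scheme; with nuisance covariates present
the test is exact only under the stronger null of full row
exchangeability.

## Reporting and decoding

Clusters are connected components of the significant set per sign,
labelled 1..K by descending extent; the peak is the max-|t| vertex and
its template coordinates fill the X/Y/Z columns (declared MNI-aligned
only for real templates).  Region names come from the parcel containing
the peak (TSV-based parcellations; label 0 → "unassigned").  ROI values
are the mask-matrix product, optionally divided by the mask sum.
Decoding correlates the binary ROI mask against each keyword map of a
decoding database over all template vertices and sorts by |r| with
lexicographic tie-breaks; a weighted statistical map can be passed in
place of the binary mask.  The shipped keyword-exclusion list is empty —
curation is data, not code.  Building a real meta-analytic database is
out of scope; the synthetic generator plants one keyword whose map equals
a chosen support.

## Synthetic cohorts

`simulate_cohort` draws `baseline + Σ(covariate × effect inside a
geodesic-hop disk) + subject random intercept + (optionally
mesh-smoothed) Gaussian noise`, i.e. data that satisfy the fitted models
exactly, in long format when sessions > 1 with the planted effect on the
session×group interaction and groups coded −1/1.  Defaults describe a
mid-sized study: 40 subjects, noise sd 1 mm around a 2.5 mm baseline,
7-hop effect disk; `effect_size` is the change per covariate unit, so a
two-group Cohen's d of 1.2 is `effect_size = 0.6` with ±1 coding.  What
the generator does *not* emulate: realistic spatial thickness priors,
medial-wall structure, scanner/site effects, non-Gaussian noise, and
spatially varying smoothness — so passing calibration here shows the
statistics are correct under their stated assumptions, not that real
cortical data meet those assumptions.

## Calibration conditions

The acceptance suite fixes these reference conditions (chosen once, with
seeds fixed):

- FWER calibration: 100 null datasets × 500 permutations on the level-1
  pair (84 vertices), N = 12 for the cross-sectional OLS harness and
  8 subjects × 2 sessions (random-intercept sd 0.5) for the sessioned
  mixed harness; noise pre-smoothed at 2× the edge length.  Rejection at
  corrected p ≤ 0.05 must land in [0.02, 0.10] for `all` and
  `within_between`, and for the same harness through RFT.
- Recovery: d = 1.2, N = 40 on the level-5 pair, 7-hop disk, 10 mm
  analysis smoothing, 50 repetitions; Dice against truth > 0.5 in ≥ 90%
  of repetitions for both correction routes (observed: ≈ 0.9 Dice for
  both).
- Mixed-model recovery: 40 subjects × 2 sessions, 84 vertices with
  independent per-vertex random intercepts (σ_b = 0.7, σ_e = 1), median
  λ̂ within 20% of 0.49.  Independence across vertices is what makes the
  median a consistent check; with a shared intercept field the vertex
  estimates co-vary and the median tracks the realised, not nominal,
  variance.

## Known limitations

- RFT accuracy degrades off the calibrated regime: low degrees of freedom
  combined with many vertices and low smoothness can turn it
  anticonservative (observed on exploratory configurations), the familiar
  ≥ 3-voxel-FWHM guidance in disguise.  TFCE permutation inference is
  exact by construction and is the safer default at small N.
- The FWHM→iterations smoothing rule is variance-matched, not an exact
  geodesic kernel; realised smoothness is quantised by the integer pass
  count.
- Only random intercepts are supported (no random slopes or crossed
  factors); non-Gaussian outcomes are out of scope.
- CIFTI dense files are read through a delegated reader; only the
  collation contract is owned here.  Volumetric projection and 3-D
  rendering are out of scope.
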