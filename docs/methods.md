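# Methods

This note documents the models, numerical choices and limitations behind
`leafvar`. It is the package's own account of its science; every empirical
number cited here is computed by the test suite or by
`scripts/acceptance.py`.

## Synthetic study design

The generator reproduces the sampling frame of a broken-stick tree
diversity experiment. An ordered pool of 8 species is recursively halved;
the contiguous blocks of size R are the species compositions at richness
level R ∈ {1, 2, 4, 8}, so every species appears in exactly one composition
per level and, with 2 plots per composition, in exactly 2 plots per level
(30 plots, 64 populations). Six trees are sampled per population and 12
leaves per tree (3 crown heights × 4 orientations). The default mortality
event reduces one monoculture population of the last species to 3 found
trees: 384 planned trees, 381 realized, 4572 leaves. Compositions are fixed
by the halving scheme; only tree-level draws are randomized. Geographic
coordinates, slope/aspect and phenology are out of scope.

Each plot also carries 36 designated central-area trees (species allocated
round-robin over the composition). These exist solely to supply the
wood-volume weights of the community analysis; leaves are never sampled
from them. They are kept in a separate table rather than as a flag on the
sampled trees because with 6 sampled trees per population the sampled set
cannot contain 36 central trees per plot.

## Hierarchical trait model

A leaf's value of trait t is

```
y = mu_s(t) + b_pop + b_tree + b_leaf
```

with independent zero-mean Gaussian effects at the population, tree and
leaf levels sharing one leaf-economics-style correlation matrix across the
five traits (SLA mm²/mg, LDMC mg/g, C %, N %, P µg/g). The tree- and
leaf-level SDs are multiplied by `exp(gamma_intra · log2 R)` and
`exp(gamma_ind · log2 R)` respectively; negative gammas shrink
within-population and within-tree variability in richer plots, which is the
effect the pipeline is designed to recover. Defaults: species means spanning
realistic subtropical broadleaf ranges (e.g. SLA 10.5–24 mm²/mg, LDMC
265–460 mg/g), per-trait SDs of roughly 4% (population), 8% (tree) and 10%
(leaf) of the trait mean, `gamma_intra = -0.3`, `gamma_ind = -0.1`. Leaf
effects are drawn independently per leaf; within-crown spatial
autocorrelation is not modeled.

## Spectral forward model

Reflectance over 350–2500 nm (1 nm step) is a fixed vegetation-like
baseline (green peak, red edge, NIR plateau, 1450/1940 nm water bands) plus
one Gaussian band per trait, `gain · (trait − ref) · exp(−(λ−c)²/2w²)`,
with band centers at absorption-plausible positions (SLA 1210, LDMC 1660,
C 1730, N 2110, P 2300 nm). The map from traits to spectra is linear, so a
latent-variable regressor can invert it up to noise. Artifacts are additive:
smooth noise (white noise convolved with a 30 nm Gaussian, SD 0.002),
per-leaf constant offsets on the VNIR (≤1000 nm) and SWIR2 (≥1801 nm)
sensors (SD 0.015 / 0.010), and rare whole-spectrum bump outliers.
Reflectance is clipped to [0, 1]. The model is a test harness: it contains
no radiative transfer, no band saturation, and its artifacts are exactly
the ones the preprocessing removes — passing tests therefore demonstrate
internal consistency of the chain, not instrument-grade accuracy on real
spectra.

## Preprocessing choices

* **Splice correction.** The middle sensor (SWIR1) is the anchor. At each
  junction the outer sensor's offset is the difference between short linear
  extrapolations of the two sides to the junction midpoint (20 nm fit
  windows, capped to the 750–1000 and 1800–1950 nm splice regions), and the
  whole outer sensor is shifted by that constant. A constant shift exactly
  inverts a per-sensor step, preserves within-sensor band shapes and first
  differences, and makes the operation idempotent. Spectra that are linear
  near the junctions pass through bit-identically; strongly curved spectra
  incur an O(curvature · window²) estimation error, which is why the fit
  windows are short.
* **Trimming.** 350–399 nm is dropped by default (sensor noise), leaving
  2101 features; the operation is inclusive on both bounds and idempotent.
* **LOF screening.** Local outlier factor per species on trimmed raw
  reflectance, `n_neighbors = 20`, flag when score > 2. The neighborhood
  size is a package default; the count of flagged spectra is
  data-dependent and not a contract.
* **Savitzky–Golay.** Window 51, polynomial order 2, derivatives per 1 nm.
  Only the valid region is returned (25 points trimmed per edge), so a
  2501-point spectrum yields 2451 filtered points and the five-channel
  augmentation (raw, SNV, SG′, SG″, SNV→SG′) yields 5 × 2451 = 12 255
  features. The augmentation is length-generic; the window/order pair is
  the value that makes the five channels of a 2501-point spectrum come out
  at 12 255.

## Calibration

Both model families standardize inputs per feature and targets per trait.
The conv-net is one valid 1-D convolution (16 filters, width 25), batch
normalization, ReLU, non-overlapping mean pooling (width 8), dense
256/64/output, trained with Adam on MSE; it is implemented in numpy,
deterministically seeded, and persisted as a single pickle archive. Mean
pooling keeps the dense stack tractable at 12 k input features and is
configurable. The PLS regressor is the fast family used for tests and
studies. Predictions are screened per species and trait against
median ± 3·MAD with the *unscaled* MAD (no 1.4826 normal-consistency
factor); the spec of the screen is plain median absolute deviations, and
the per-species grouping matches the downstream per-species imputation.
Missing cells are then imputed per species by iterative rank-2 SVD
reconstruction of the restandardized table (means/SDs recomputed each
iteration, observed cells restored after each step, convergence when the
largest change drops below 1e-8; non-convergence warns rather than fails).

## Trait axes

PCA is computed on centered/scaled traits via SVD. Axis signs follow the
convention that the trait with the largest |loading| on an axis loads
positively, which fixes score reproducibility without asserting any
particular loading pattern. Horn's parallel analysis compares observed
correlation eigenvalues with the mean eigenvalues of `n_iter` same-shape
standard-normal datasets: `adjusted_k = observed_k − (random_k − 1)`,
retained while > 1. The mean rule implies that for pure noise every
adjusted eigenvalue sits at ~1 and retention of the first axis is a coin
flip; a `quantile` option (e.g. 0.95) gives the strict behavior where noise
retains nothing. Eigenvalues of wide blocks (more wavelengths than leaves)
are computed from the SVD of the standardized data, which is what makes
recursive segmentation affordable. Pipeline order is fixed as
predict → MAD screen → impute per species → PCA.

## Spectral segmentation

The recursion computes parallel analysis on the current wavelength block;
when more than one component is retained, wavelengths are split into two
groups by spectral clustering (normalized cuts, k-means label assignment)
on the squared Pearson correlation between wavelength profiles — squared so
that negatively coupled bands count as coupled. Each group is broken into
maximal contiguous runs before recursing, so reported segments are always
contiguous even though the clustering itself does not enforce contiguity.
Terminal blocks with retention ≠ 1 are flagged degenerate and excluded
from spectral traits. Guards: blocks narrower than `min_width = 5` and
deeper than `max_depth = 12` stop the recursion; single wavelengths count
as trivially one-component. All parallel-analysis and clustering
randomness derives from one seed.

## Trait probability densities

All TPDs in a comparison share one regular grid spanning the pooled points
plus 5% padding per side, 50 cells per dimension by default (2500 cells in
2-D). The kernel is Gaussian with a full bandwidth matrix H chosen by a
two-stage plug-in: data are sphered with their sample covariance; the five
fourth-order integrated density derivative functionals are estimated with a
normal-scale scalar pilot (`g = n^(-1/(d+6))`) via Hermite-polynomial
derivatives of the product Gaussian; and the asymptotic MISE with those
functionals in its bias term is minimized over Cholesky-parametrized SPD
matrices (BFGS, then a Nelder–Mead polish so the optimum is tight enough
for exact scale equivariance). Samples with n < 5 or singular covariance
fall back to the scaled-covariance (normal-reference) rule with a floored
covariance, and the fallback is flagged on the resulting TPD. Density is
evaluated at cell centers, multiplied by cell volume and renormalized over
the grid; thresholding removes the lowest-density cells while the removed
mass stays ≤ 5% (never overshooting past the crossing cell) and
renormalizes again. If a degenerate sample's kernel is so narrow that every
cell-center evaluation underflows, each point's mass is placed in its
containing cell, preserving the "tiny FRic" semantics of coincident
points. A brute-force double-loop kernel evaluation reproduces the gridded
estimator to < 1e-10 (tested).

Units: a tree's TPD comes from its ≥ 5 retained leaf scores; a
population's TPD from the bootstrap mean scores (mean of B = 999 resample
means by default; B is a package default, and the bootstrap mean converges
to the arithmetic mean) of its ≥ 3 trees — the floor of 3 keeps the 3-tree
mortality population usable while leaving KDE barely identified; both
floors are package defaults chosen for KDE stability. Intraspecific
overlap is the mean pairwise Σ min over a population's tree TPDs.

## Community assembly and null models

Inside the community framework a population TPD is the **equal-weight
mean** of its member tree TPDs (each tree TPD already sums to 1, so the
mean does too; plain summation would need renormalization anyway and
weighting by tree size is not modeled). The community TPD is the
weight-summed population TPD with species weights proportional to the
clamped central-area wood volume `WV = 0.5412 − 0.1985 · BA · H`. The
formula goes negative for BA·H ≳ 2.7 m³; it is implemented verbatim with
configurable coefficients, negative volumes clamp to zero for weighting
(raw values are still reported), a plot whose weights all clamp falls back
to equal weights with a warning, and an alternative form-factor mode
`WV = f · BA · H` is selectable. Community TPDs are not re-thresholded.

The four null schemes permute, within species (or within population for
the restricted scheme), population TPDs across plots, trees across
populations, or leaf records across trees, always preserving plot
composition and per-unit counts. Population- and tree-level schemes reuse
the precomputed TPDs they merely relocate — this equals full recomputation
because a TPD depends only on its own unit's points — while leaf-level
schemes recompute tree TPDs (including bandwidths) per draw. SES follows
`(FD_obs − mean FD_sim)/SD FD_sim`; a zero null SD is flagged undefined
rather than propagated as ±inf. Convergence of a null distribution is
summarized by running mean/SD with a drift flag when the last-decile mean
moves more than 5% of the final SD.

## Validation studies and problem sizes

* **SES calibration**: 7 default designs with population effects and
  richness sensitivities set to zero (trees exchangeable within species),
  random-tree scheme, 500 draws per plot → ~210 plot-level SES values;
  their mean should be ~0 and SD ~1.
* **Slope recovery**: 50 design seeds per arm; traits → PCA → bootstrap
  tree means (B = 100 in the study for speed) → population TPDs → FRic →
  species-demeaned OLS slope on log2 richness. `gamma_ind` is held at 0 in
  both arms so the tree-level signal is isolated and the `gamma_intra = 0`
  arm is an honest coin flip.
* **Segmentation recovery**: 20 seeds per block count; 160 leaves; 2 or 3
  planted 50 nm blocks, each driven by one latent factor with a smooth
  loading profile, noise SD 0.05.
* **Calibration**: 700 leaves, low-noise artifact-free forward spectra,
  trimmed and augmented, PLS with 12 components on a stratified 75% split.

These sizes are the package's test-scale choices; all of them can be
raised through the studies' keyword arguments.

## Known limitations

* The forward model is linear and its artifacts match the preprocessing
  exactly; results do not establish performance on real spectrometer data,
  nonlinear trait–reflectance relationships, or non-Gaussian outliers.
* The plug-in bandwidth uses a scalar normal-scale pilot on sphered data
  rather than the fully iterated pilot of the reference selectors; for the
  small per-unit samples used here (6–12 points) the difference is well
  inside the Monte-Carlo noise of the indices.
* Mixed-effects inference (likelihood-ratio tests, standardized betas,
  piecewise SEM) is deliberately out of scope; `richness_trend` is a
  recovery diagnostic, not a substitute for those models.
* TPDs are limited to 1 or 2 dimensions; higher-dimensional trait spaces
  would need a different grid strategy.
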