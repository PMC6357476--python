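# Methods

This note documents the models, algorithms, defaults and known limits of
the package. It states no empirical result that the test suite and
`scripts/acceptance.py` do not themselves compute.

## Synthetic cross-section images

The generator draws a flatbed-scan-like 8-bit grayscale image: a
piecewise-constant base (background / bright rind annulus / darker pith
disc, assigned by pixel-centre membership in two concentric ellipses)
plus one additive anisotropic Gaussian per vascular bundle,
`A·exp(−½ dᵀΣ⁻¹d)`, plus i.i.d. Gaussian noise, clipped to [0, 255] and
rounded. Coordinates follow raster convention: position (x, y) =
(col, row) × scale, origin at the top-left pixel centre, so physical
conversion is a single multiplication.

Bundle centres are placed by rejection sampling with a Poisson-disc-style
minimum spacing (default 0.15 cm), capped at 10,000 attempts; infeasible
spacing raises an explicit error naming the constraint. Centres are kept
at least 2·σ_max inside the pith ellipse so bundle mass does not leak
into the rind. Per bundle, σ_x and σ_y are drawn uniformly from the
configured range and the principal axes are rotated by a uniform angle;
the returned ground truth records exact centres, covariances and
amplitudes, and the analytic rim area at fraction *f* is
`π·2·ln(1/f)·√(det Σ)`.

Defaults (512 px² canvas at 0.005 cm/px; stalk semi-axes 1.1 × 1.0 cm;
rind 0.30 cm; 30 bundles; amplitudes 60–100 over a pith level of 90;
σ 0.012–0.020 cm; noise SD 6) give a stalk diameter of 2.2 cm, a rind
thickness near the centre of the reported range for field panels, FWHM
bundle areas near 1×10⁻³ cm², and a per-bundle signal-to-noise ratio of
at least 10. Real scans differ in ways the generator deliberately omits:
uneven illumination, staining variation, non-elliptical boundaries,
bundle-free lacunae, and texture within rind and pith. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated model, not robustness to every real-scan artefact.

## Morphometry

**Segmentation.** Otsu (or fixed) thresholding, hole filling, largest
connected component, sub-pixel contour at the 0.5 level; enclosed area by
the shoelace formula. A component touching the image border is an error:
a truncated stalk cannot be measured. With a three-level image Otsu may
threshold between pith and rind; hole filling makes the result identical
to the whole-stalk mask, so segmentation does not depend on which side of
the pith level the threshold lands.

**Diameter** is the exact maximum pairwise distance between boundary
points, computed on the convex hull (the diameter of a set is attained on
its hull); tests pin equality with the O(n²) brute force.

**Rind thickness.** Rays are cast from the mask centroid; along each ray
the boundary radius R comes from the mask, the rind reference brightness
is the mean over the outermost ~5% of the ray (skipping the two mixed
edge pixels), and the transition is the outermost sample whose brightness
falls below θ·reference (θ = 0.7 by default). Thickness is the mean of
R − transition over rays; rays without a transition are excluded and more
than 50% failed rays is an error (e.g. a uniform disc with no annulus).
72 rays with 0.5 px radial sampling balance accuracy against cost. For an
elliptical stalk the radial path is slightly oblique to the boundary
normal, biasing each ray's depth upward by ~1/cos of the obliquity angle;
at the default 1.1:1.0 axis ratio this is well under the 10% recovery
tolerance the tests enforce.

**Bundle detection.** Local maxima of the Gaussian-smoothed image
(σ = 0.0075 cm ≈ 1.5 px) inside the pith — the stalk mask eroded by the
measured rind depth plus two pixels — with an absolute prominence floor
of 25 intensity units above the pith median. `peak_local_max` is used
only as a coarse thinning step because its `min_distance` is a Chebyshev
(square-footprint) criterion that over-suppresses diagonal neighbours
near the limit; the spacing floor (default 0.10 cm) is enforced by a
greedy brightest-first pass using true Euclidean distances.

**Gaussian fit.** Nonlinear least squares of
`b + A·exp(−½(x−μ)ᵀΣ⁻¹(x−μ))` with Σ parameterised by its Cholesky
factor, so every iterate is symmetric positive definite; bounds keep the
factor entries between 0.3 px and the window radius. The support is a
disc (radius = 0.8 × spacing floor) with a mild radial Gaussian taper,
and — when the caller provides the pith mask, as `measure_section` does —
is further intersected with the pith: without this, fits of bundles near
the pith edge latch onto the rind band, which is an order of magnitude
brighter than any bundle. Initialisation: μ at the detected peak,
baseline at the support median, A from the centre pixel, Σ isotropic from
the second moments of the positive excess brightness. Tolerances
(xtol = ftol = gtol = 1e-12, ≤ 200 iterations' worth of evaluations) are
tight enough that on noiseless data the closed forms hold to 1e-9, which
a looser 1e-8 objective tolerance did not reliably reach. A fit is
"converged" only if the optimizer succeeded and the amplitude exceeds the
detection floor; only converged fits contribute to bundle count, density
and mean area.

**Rim convention.** The bundle rim is where the fitted surface drops to a
fraction *f* of the peak *above baseline*; *f* = 0.5 (FWHM) by default.
Radii follow as `rᵢ = √(2·ln(1/f)·λᵢ)` and the area as `π·r₁·r₂`. This
makes radii and area invariant to amplitude rescaling, which the tests
assert. *f* is configuration, not a fact about any particular scanner.

**Density denominator.** Bundle density divides the converged-bundle
count by the whole cross-section area, not the pith area. Units of cm⁻²
reported for whole sections, and the negative density–diameter
correlations seen in field panels, are both consistent with a
whole-section denominator; the pith-only alternative would need the rind
subtracted and is intentionally not offered to keep the trait definition
unambiguous.

## Trait statistics

The observation model is the balanced mixed model
`y_ijk = μ + G_i + E_j + R_k(j) + GE_ij + ε_ijk` with independent normal
random effects. Components are estimated by equating the balanced ANOVA
mean squares to their expectations:

    σ̂²_e     = MS_err
    σ̂²_GE    = (MS_GE − MS_err) / r
    σ̂²_G     = (MS_G − MS_GE) / (r·y)
    σ̂²_R(E)  = (MS_R(E) − MS_err) / g
    σ̂²_E     = (MS_E − MS_GE − MS_R(E) + MS_err) / (r·g)

Negative solutions are truncated at zero and flagged — standard
method-of-moments practice that also keeps h² in [0, 1]. On balanced data
with interior solutions these estimators coincide with REML; the test
suite pins agreement with an independent `lme4` REML fit (run once, its
components frozen into the test) to well within 5%. A general REML engine
for unbalanced data is deliberately out of scope: unbalanced input is
rejected with an error rather than silently approximated. With a single
environment the GE component is not estimable and is fixed at zero,
flagged on the result.

Heritability is computed on an entry-mean basis,
`h² = σ²_G/(σ²_G + σ²_GE/y + σ²_e/(r·y))`; environments play the role of
years. BLUPs use the balanced-design identity
`BLUP_i = h²·(ȳ_i·· − ȳ···)`, and reported trait values are grand mean +
BLUP. Whether replicate effects should additionally enter the shrinkage
is a modelling choice on which reasonable mixed-model parameterisations
differ; the balanced-design shrinkage above is this package's declared
convention, and the BLUP deviations always sum to zero by construction.

The G×E F-test is MS_GE/MS_err with ((g−1)(y−1), (g−1)·y·(r−1)) degrees
of freedom. Fold differences are rounded to two decimals and percent
reductions to the nearest integer (half away from zero), matching how
such trials are conventionally reported; fold is undefined (flagged) for
non-positive minima. Spearman correlations use midranks and
pairwise-complete observations with a three-genotype floor per pair;
constant vectors yield a flagged NaN.

## Genotype QC

The calling rule is applied literally: depth ≥ 5 (inclusive), allele
fraction > 5% (strict), allele count ≥ 2 (inclusive); exactly one passing
allele is a call and any other outcome — including an apparent
heterozygote in an inbred panel — is missing. Fractions are computed on
raw counts, before any allele is removed. Tests pin every boundary and
prove exhaustive agreement with a brute-force restatement of the rule
over all count vectors of depth ≤ 12.

Missingness ceilings are inclusive (a site at exactly 80% missing is
discarded); the MAF floor is strict (a site at exactly 0.05 is kept).
Both filters are idempotent and order-independent, which the tests
assert. Imputation accuracy is scored, per individual, over cells that
were missing before imputation and are non-missing in both the imputed
and reference matrices; a flag widens this to all shared non-missing
cells. Individuals with no comparable cells are excluded from the mean
and reported.

`bonferroni_neglog_threshold(m, α) = −log10(α/m)` is arithmetic only. For
m = 899,784 and α = 0.05 it gives 7.2552; published analyses of that
marker panel quote 7.55, which the formula cannot produce for any stated
(m, α) in range — the effective test count behind that figure is unknown.
The pipeline therefore treats the genome-wide significance cutoff as
configuration with the formula output as default, and a test documents
the discrepancy.

## Pileup simulation

Per site, two distinct alleles and an alternate-allele frequency p;
individuals receive 0/1/2 alternate copies at Hardy–Weinberg proportions
(the spec'd per-site frequency closes over genotypes naturally this way).
Depth is Poisson; heterozygotes emit reads 50:50; each read flips to a
uniformly chosen other base with the error probability. Truth genotypes
are returned alongside, hom as a single symbol and het as "X/Y", matching
the haploid-style calling convention for inbred lines.

## Problem sizes and determinism

The recovery experiments run at 500 genotypes × 3 environments × 2
replications (20 seeds) for heritability and ten 512×512 sections with 30
bundles for morphometry — sizes at which the estimators' sampling error
is comfortably inside the tolerances being checked while the whole suite
and the acceptance script each complete in seconds. All generators take
explicit integer seeds and are bit-reproducible; the CLI writes the seed
and a config hash into every output's provenance header, and confines the
timestamp to its own header line so repeated runs are byte-identical
apart from it.

## Known limitations

* The image model is an idealisation (three intensity levels + Gaussian
  blobs); the scanner/illumination model of real acquisitions is not
  simulated, and the rind-thickness and bundle-detection operators are
  reconstructions of standard practice, not reimplementations of any
  specific lab's software.
* Unbalanced trials are rejected, not modelled.
* No imputation algorithm is provided — only the accuracy metric for
  evaluating one.
* Genotype calls are haploid-style (inbred convention); heterozygous
  calls are by design reported as missing rather than as diploid
  genotypes.
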