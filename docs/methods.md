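# Methods

This note records the models, numerical choices and limitations behind the
package, at the level of detail a maintainer or reviewer needs.

## Synthetic data model

The generator stands in for cell-body stained histology. An area is a
`LaminarModel`: relative layer widths over normalised cortical depth
(summing to 1) and a mean GLI per layer, giving a piecewise-constant
density profile; an optional moving average mimics gradual laminar
transitions. Ribbons are sequences of such areas. Noise is i.i.d. additive
Gaussian on GLI values, clipped to [0, 1] — the simplest model consistent
with treating block averaging as a signal-to-noise device. The default
noise level is `noise_sd = 0.03`: GLI values from 16 × 16 px windows of a
Bernoulli cell field have a binomial standard deviation of about
√(0.25/256) ≈ 0.03, so this matches the sampling noise the windowing
itself produces. The default two-area demo ribbon has 162 traverses
(76 + 86) with its border after traverse 76, and the contrasting area
differs by ≥ 0.15 in two layer densities.

Binary cell images are Bernoulli fields whose success probability is the
laminar density at each pixel's depth, on a flat or circular-arc ribbon
(curvature = 1/outer radius; self-intersecting geometries are rejected).
Contour polylines are returned in pixel-centre coordinates, so the tissue
boundary runs half a pixel outside the outermost foreground row.

Subject label volumes are rigid integer-voxel translations of a canonical
disjoint area layout, one Gaussian displacement of scale `jitter_mm` per
subject and axis; labels shifted off the grid are clipped with a warning.
Ten subjects with 2 mm jitter is the default family. Nonlinear warps,
staining artefacts and realistic cell morphology are deliberately out of
scope; what passing tests show is that the statistics and geometry of the
pipeline are correct, not that the generator reproduces every property of
real sections.

## GLI and profile extraction

`compute_gli` uses non-overlapping windows by default (the field size is
what the method fixes; the stride is configurable, and overlapping strides
give denser depth sampling). Trailing partial windows are dropped. With
window-aligned images, the mean GLI equals the overall foreground fraction
exactly (integral-image arithmetic; exactness in floating point holds for
power-of-two windows whose fractions are dyadic).

Cortical depth is the solution of the Laplace equation with the outer
contour at 0, the inner at 1 and no-flux ends. The solver uses
Shortley–Weller finite differences: grid links crossing a contour polyline
get fractional arm lengths (clamped at 0.02 px), so the boundary enters at
sub-pixel accuracy instead of its rasterisation. The sparse system is
solved directly; the scaled residual must be below 1e-8 or the solver
raises. Against closed forms the field is exact on an axis-aligned plate
and accurate to ~3 × 10⁻⁴ (max) on an annulus of 40 px thickness.
Traverses integrate dx/dt = ∇φ/|∇φ|² (so t tracks depth) with RK2 and
fixed steps, seeded at equidistant arc length on the outer contour;
profiles sample the GLI image bilinearly at 100 equidistant
normalised-depth bin centres. GLI windows straddling the ribbon edge are
renormalised by their in-tissue coverage (tissue = pixel centres between
the contours), so sampled values are densities of tissue rather than of
window area. Traverses that leave the ribbon before reaching the inner
contour are excluded and counted.

Accuracy note: the 16 px window blurs the profile over ~window/thickness of
normalised depth around layer boundaries. On a 320 px-thick synthetic
ribbon the mean extracted profile matches the generating step function to
RMS < 0.03; thinner ribbons blur more.

## Border detection

Feature vectors are weighted central moments with the profile as weight
over depth; derivative features use the absolute first difference on
midpoint abscissae (weights must be non-negative for weighted moments).
Degenerate cases: an all-zero profile is an error; zero spread with
non-zero weights reports skewness/kurtosis 0 with a warning; an all-zero
derivative pins the derivative centroid at the grid centre with zero
spread, also warning.

The Mahalanobis distance uses the pooled within-block sample covariance of
per-profile feature vectors. Features are standardised internally over the
ribbon before the computation — mathematically a no-op (Mahalanobis
distances are invariant under common affine feature maps) that
canonicalises the floating-point path, so equivalent inputs agree to
~1e-11. Blocks whose member features are bitwise identical are assigned
distance exactly 0 without touching the (singular) covariance. Optional
shrinkage blends the pooled covariance toward a scaled identity for
near-singular cases; it is 0 by default and required only when
2b − 2 ≤ 10. Significance: T² = (b²/2b)·MD², F = (2b − p − 1)/((2b − 2)p)·T²
with p = 10, Bonferroni-multiplied by the number of sliding positions per
block size (the consensus rule below handles multiplicity across block
sizes). Under a multivariate-normal null this calibration is exact; the
test suite verifies type-I error and p-value uniformity by simulation.

Border consensus: per block size, significant local maxima (plateaus
collapse to their midpoint, lower index on even plateaus; endpoints cannot
be confirmed and are dropped) are merged across block sizes within a
3-traverse window at their median position; a merged candidate needs
support from at least half the block sizes (rounded up, i.e. 7 of 13 for
blocks 12–24). The block-size range default is 12–24, configurable, since
narrower ranges are equally legitimate. With the default study conditions
the detector recovers the true border within ±3 traverses in ≥ 95 % of
seeded runs and reports no border on homogeneous ribbons in ≥ 98 %.

## Volumetry

Cavalieri volume = Σ areas × thickness × interval × shrinkage; linear in
each factor by construction. Permutation tests use the mean difference
(the classical statistic when none is specified), the add-one Monte Carlo
p estimator, and 10 000 permutations by default; the pooled sample is
sorted before permuting so the p value is exactly invariant to group
relabelling and common shifts. Hemisphere comparisons are treated as
paired within brain (sign-flip permutation) because both hemispheres come
from the same brain; gender comparisons are unpaired on per-brain mean
fractions. Correction across areas is Benjamini–Hochberg FDR by default
with Bonferroni selectable — both appear in the literature for this
analysis, and FDR is the less conservative, better-calibrated default.

## Atlas operations

Probability maps are per-voxel subject counts over n subjects; affines
must agree to 1e-6 (no resampling — inputs are assumed co-registered).
The MPM takes the voxelwise argmax; exact probability ties (probabilities
are multiples of 1/n, so ties are exact) are resolved by the highest mean
probability over the voxel's 26-neighbourhood (6/18/26 configurable,
centre excluded); a still-tied voxel falls to the lowest area id and is
counted in the output. The 40 % threshold applies only where the winning
area has no mapped competitor at that voxel (runner-up probability zero),
i.e. at borders with not-yet-mapped cortex; contested voxels keep their
argmax label at any probability. Centres of gravity are
probability-weighted means of world coordinates over non-zero voxels.
Map–map correlation is Pearson over the union of both maps' non-zero
voxels by default; the domain is the main free parameter of that statistic
and can be set explicitly (e.g. whole grid). Coordinate assignment rounds
world coordinates to the nearest voxel and returns all areas with
probability ≥ 0.2, descending.

## Similarity

Mean area features average the feature vectors of 45 profiles sampled
without replacement from each of three sections (seed-deterministic).
Distances are Euclidean on the raw 10-vector by default; a z-scoring flag
exists because the moments differ in scale by orders of magnitude, and
which features dominate is a real analytical choice. MDS is metric SMACOF
minimising normalised stress-1, initialised with the classical (Torgerson)
solution plus 7 random restarts; on exactly 2-D-embeddable distances the
classical start is already optimal and stress reaches ~1e-16. UPGMA is
implemented directly (size-weighted average linkage, node height = merge
distance/2, lexicographically smallest pair on ties, Newick export with
ultrametric branch lengths); scipy's average linkage serves as an
independent cross-check in the tests, as does exhaustive merge enumeration
for n ≤ 6.

## Pipeline and reproducibility

All randomness flows from one master seed through CRC-tagged
`SeedSequence` stage seeds, so identical configurations give byte-identical
outputs (verified down to the written NIfTI). The demo pipeline runs a
two-area ribbon through border detection and a two-area, ten-subject
label-volume family through pmaps, MPM and centres of gravity.

## Problem sizes used in validation

Border recovery uses 100 seeded 162-traverse ribbons and specificity 200;
Hotelling calibration 2000 null replicates (b = 20, p = 10); MPM oracle
equivalence 50 random 20³ families; volumetry null calibration 200 tables
of 10 brains × 2 hemispheres × 7 areas at 1000 permutations; the
two-family clustering check 50 seeds of 7 synthetic areas. These sizes
give Monte Carlo standard errors comfortably below the margins being
tested while keeping the whole validation run around half a minute.

## Known limitations

- The generator's piecewise-constant laminar profiles and translation-only
  subject jitter are idealisations; performance on real histology depends
  on staining quality, contour placement and registration accuracy, none
  of which are modelled.
- The depth-field solver assumes the two contours bound a simply connected
  ribbon; pathological self-intersecting contours are not repaired.
- Window blur limits profile fidelity on ribbons thinner than ~10 GLI
  windows; the profile RMS guarantee is stated for 20-window ribbons.
- Exact-zero guarantees (GLI conservation, identical-block MD) hold for
  dyadic window sizes and bitwise-identical inputs respectively; away from
  those conditions agreement is to ordinary floating-point accuracy.
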