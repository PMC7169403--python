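# Methods

`gaborhough` marks the endocardial (inner) border of the left ventricle (LV)
on a 2-D grayscale ultrasound-like still. The procedure is a pipeline of
four stages — Gabor-filter region-of-interest (ROI) localization, an
anisotropic generalized Hough transform (GHT) with a guided deformable
template, ranking of candidate poses by accumulator rate, and an SVM
confidence score computed from accumulator-space statistics. Because
clinical echocardiograms cannot be redistributed, a seeded phantom
generator provides ground-truthed inputs for every test and bench in the
package.

## Gabor ROI localization

A Gabor kernel is a sinusoid under a Gaussian envelope,

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) cos(2 pi x' / lambda + phi),

with `x', y'` the coordinates rotated by the filter orientation. The
envelope width `sigma` is never set directly; it follows from the
half-response spatial-frequency bandwidth `b` (octaves) through

    sigma / lambda = (1/pi) sqrt(ln 2 / 2) (2^b + 1) / (2^b - 1),

which at the default `b = 1` gives `sigma = 0.56 lambda`. The inverse
formula recovers `b` from `sigma/lambda`; the two are mutual inverses to
1e-9 over `b` in [0.25, 4], and `b` is undefined at or below the pole
`sigma/lambda = sqrt(ln 2 / 2)/pi ≈ 0.187`.

The default bank pairs 4 orientations {0, pi/4, pi/2, 3pi/4} and 2
wavelengths {8, 16} px, each as an even/odd quadrature pair combined into a
phase-invariant magnitude; the response is the pointwise maximum over the
bank. `gamma = 0.5`, `b = 1`, kernel radius `ceil(3 sigma)`, reflect
padding (FFT convolution). The ROI is the largest connected component of
the Otsu-thresholded response after a morphological closing (disk radius
2); its bounding box, padded by an 8 px margin, limits both the edge points
and the candidate reference positions of the GHT. If thresholding leaves
nothing (flat response), the pipeline falls back to a whole-image search
and flags the result.

## Templates

A boundary template is an ordered point list with a reference point (the
barycenter) and a per-point edge orientation (contour normal mod pi).
Templates can be extracted from a hand-drawn binary sketch — largest
component, skeletonization, path tracing, 1 px arc-length resampling — or
built analytically. The canonical LV template is the lower half of an
ellipse (a U open toward the scan-sector apex) sampled at 1 px spacing:
the left limb models the septal wall, which is usually well visualized and
serves as a thin (half-width 1 px) rigid guidance segment; the right limb
models the lateral wall and is a thick deformable band (default half-width
6 px, matching a plausibly uncertain wall position).

### Band deformation

After the GHT fixes the pose, each posed lateral point may slide along its
posed unit normal by a scalar offset, discretized at 1 px steps within
`+-half-width * mean(Sx, Sy)`. The chosen offsets maximize

    sum_i G(p_i + d_i n_i) - beta sum_i (d_{i+1} - d_i)^2

where `G` is Sobel gradient magnitude (bilinearly sampled) and
`beta = 0.1 / px^2`. The optimum is found exactly by dynamic programming
along the polyline. Ties prefer smaller |offset|, then negative offsets,
so a gradient-free image returns the posed polyline unchanged; as
`beta -> inf` the offsets become constant. Normals for the deformation are
taken from the signed tangent field of the ordered polyline (rotated
+pi/2), not from the mod-pi orientations used for R-table binning — the
mod-pi reduction can flip direction along a contour, which would corrupt
the smoothness term.

## Anisotropic GHT

A pose is `a = (y, S, theta)`: reference position `y`, per-axis scales
`S = (Sx, Sy)`, rotation `theta`. The R-table stores, for each template
point, the polar displacement `r = y - x_B` in the bin of its orientation
(`pi/n_bins` wide; `n_bins = 36`, i.e. 5 degrees). At detection time an
edge point with orientation `phi` under hypothesis `(S, theta)` looks up
bin `(phi - theta) mod pi` and votes at
`round(x_B + Rot(theta) diag(S) r)` (round-half-to-even) for every stored
entry. Votes accumulate in an int32 array over (Sx, Sy, theta, y, x);
positions span every pixel of the ROI bounding box. Orientation matching
ignores the shear that anisotropic scaling applies to normals (lookup
shifted by theta only) — the standard GHT approximation; the stamping
helper uses the same convention, so a template stamped at any grid pose is
recovered with rate exactly equal to its point count.

Edge points are Sobel pixels whose gradient magnitude reaches the 75th
percentile of the nonzero magnitudes inside the ROI. A higher (90th)
percentile was tried first and keeps too few boundary pixels: the
survivors cluster on the highest-contrast arc, under-constraining the
scales, and noise-free pose recovery dropped to 5/12; at the 75th it is
12/12 with unchanged runtime. The threshold is attained, not exceeded
strictly, so ideal step edges (all pixels at exactly the threshold) are
kept.

The default search grid is `Sx, Sy in [0.85, 1.15]` step 0.05 and
`theta in [-pi/6, pi/6]` step `pi/36` — about 640 pose cells, which a
256x256 image processes in roughly a second. A millesimal scale grid can
be expressed through the same `(min, max, step)` configuration triples
when the extra resolution is worth the (roughly 3500x) cost; the coarse
default reflects that the band deformation absorbs sub-step pose error.

Ranking: cells sort by rate descending, ties broken lexicographically on
(theta-bin, Sx-bin, Sy-bin, y, x) ascending; greedy non-maximum
suppression drops candidates whose (x, y) distance to an accepted
detection is strictly below the suppression radius (default 5 px, so a
radius of 0 suppresses nothing). The pipeline reports the ten best
candidates and selects the first. The report line is

    The best matching was found for scale %.6f and angle %.3f in position (%d, %d) with rate %d

printing one scale when `Sx = Sy` and appending both otherwise. The rate
is the raw integer vote count, not normalized.

## Confidence scoring

An accumulator is summarized into 11 statistics: max rate, mean, variance,
peak-to-second-peak ratio (second peak outside the suppression radius of
the first; capped at 1e6 when zero), entropy of the normalized vote
distribution (natural log), the argmax pose coordinates normalized to
their grid ranges, and the fraction of votes within the suppression radius
of the peak. Summary statistics, rather than the flattened accumulator,
keep the feature length independent of grid resolution.

The classifier is a support vector machine with a cubic kernel
`(x . x' / s^2 + 1)^3`; the "automatic" kernel scale `s` is the median
pairwise Euclidean distance between the standardized training vectors.
Features are standardized to zero mean and unit variance; `C = 1`. The
fitted decision function (support vectors, dual coefficients, intercept)
is stored explicitly and evaluated directly, so a model serialized to JSON
and reloaded scores bit-identically. Confidence is the logistic map of the
signed margin, 0.5 at the decision boundary. Evaluation uses leave-one-out
cross-validation (LOOCV).

Labels for synthetic training follow a geometric rule: a marking is
"correct" when its mean boundary error against ground truth is at most
3 px. Both feature sources — the accumulator of the whole-image search and
the ROI-restricted one — are scored against this one labeling, so the
comparison isolates the effect of the restriction.

## Phantoms

A phantom renders, at 8 bit: background 8, scan-sector fill 55, cavity 22,
myocardial wall 210, with the lateral (right) wall linearly dimmed by
`lateral_attenuation` in [0, 1]. The sector is a fan from an apex near the
top edge; the cavity is a full ellipse whose lower half carries the wall
band (thickness `wall_thickness`), leaving the upper half open toward the
valve plane. The ground-truth boundary is the posed canonical template and
is reproduced by the pose to better than 0.5 px by construction. Speckle
is multiplicative: `image * (1 + speckle_scale * n)` with `n` a
unit-variance Gaussian field smoothed at `sigma = 1 px` — visually
speckle-like, fully seeded, and making no claim of physical fidelity (no
point-spread function, no attenuation physics, no cine loops). Optional
distractors paint dimmer (120–170) U-shaped chamber-like bands in the
sector's far field, emulating the other chambers of an apical view; they
never overwrite the cavity or wall. Distractors matter because Hough
voting is amplitude-blind: a complete dim structure can out-vote a
degraded bright wall in a whole-image search, while the
amplitude-sensitive Gabor response still selects the true wall — the
clutter the ROI restriction exists to remove.

What passing on phantoms does not show: robustness to real speckle
statistics, probe-dependent shading, valve and papillary-muscle anatomy,
or out-of-plane motion. The phantoms probe the geometry and the voting
logic, not ultrasound physics.

## Benches and problem sizes

Pose-recovery benches use 25 noise-free 256x256 phantoms with poses drawn
on the search grid (positions +-10 px, scales {0.90..1.10}, rotations
+-3 grid steps), and the same count at `speckle_scale = 0.3` for the
marking-error bench. The confidence bench draws 48 phantoms per seed at
128x128 with continuous (off-grid) poses, speckle U(0.1, 0.6), lateral
attenuation U(0, 0.7) and 2 distractors — mixed image quality so both
correct and incorrect markings occur — and compares LOOCV accuracy of the
SVM on restricted-space versus full-space features as the mean over five
seeded benches. The 128x128 bench size keeps a five-bench evaluation in
the low minutes while leaving enough boundary support for the method to
operate.

## Numerical choices and degenerate inputs

- Coordinates are 0-based `(x = column, y = row)`, y increasing downward,
  everywhere.
- Vote locations round half to even (`numpy.rint`); the brute-force oracle
  in the tests uses the identical convention.
- All-zero accumulators rank to an empty candidate list and cannot be
  featurized (explicit error); a blank image raises a "no edges" error
  with its own exit code.
- LOOCV folds whose training split loses a class are skipped (counted as
  misses through the denominator).
- Balanced random labels push LOOCV *below* 50% (the held-out label is
  always the training minority); the permutation test asserts an
  asymmetric band accordingly.
- The sketch tracer orders skeleton pixels greedily from an endpoint (or
  an arbitrary start on closed curves); branching sketches follow the
  nearest-neighbor branch and drop the rest.

## Known limitations

- The scale–position ambiguity of a U-shaped template (shrink `Sy`, shift
  `y` down) is resolved only by limb support; at 128x128 the strict
  one-grid-step pose criterion needs more boundary pixels than a noisy
  image provides, even when the implied boundary is within ~1.5 px. The
  band deformation largely absorbs this, which is why marking error is
  the more stable metric.
- Anisotropic scaling shears edge normals; the R-table lookup ignores
  this. At the default scale range (+-15%) the induced orientation error
  stays below the 5-degree bin width for most of the contour.
- The confidence features are weak individual predictors (AUC ~0.5-0.67
  on the benches); the restricted-vs-full ordering is a small averaged
  effect, not a per-bench guarantee.
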