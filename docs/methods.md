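# Methods

## Problem and model

Metaphase spindles in cultured mammalian cells (e.g. MG132-arrested HeLa) are
imaged live in widefield with very sparse axial sampling — typically three
z-slices 2 µm apart every 3 minutes, with lateral pixel sizes of
0.04–0.07 µm. spindlekit reconstructs a 3D model of the spindle and the cell
cortex from such data and quantifies spindle motion relative to the cortex.

Both structures are modeled as ellipsoids:

- **Cortex.** Boundary pixels of the per-slice cortex masks are lifted to
  their physical planes (z = slice index × z-step) and enclosed with a
  minimum-volume enclosing ellipsoid (MVEE). Mitotic cells are near-spherical
  but not circular — the default synthetic cortex uses an in-plane
  eccentricity of 0.30, the median observed for mitotic cells — so an
  ellipsoid rather than a sphere is the base model.
- **Spindle.** The spindle mask is burned onto the raw fluorescence image of
  the brightest slice; the top 30 % brightest masked pixels are kept and each
  is assigned an axial offset by inverting the axial profile of the
  microscope PSF (below). The resulting 3D point cloud is enclosed with an
  MVEE whose principal axes define the spindle's length (pole-to-pole), width
  and height axes; the six axis endpoints are the tracked landmarks.

## MVEE

`fit_mvee` implements the dual determinant-maximization program with
Wolfe–Atwood coordinate ascent (Frank–Wolfe "add" steps toward the worst
point plus away steps shrinking over-weighted points), stopping when the
maximal lifted Mahalanobis value is within (1 + tol) of its optimum d + 1
(default tol 1e-4, max 10 000 iterations). This converges to machine-level
volume accuracy in milliseconds for the point-cloud sizes that arise here.
An independent SLSQP solution of the same convex program
(`reference.mvee_volume_detmax`) is used as a cross-check oracle in tests
only. Axis labels are made deterministic by sorting semi-axes descending,
making the first nonzero component of each orientation column positive, and
flipping the last column if needed for det +1.

Degenerate clouds (coplanar/collinear) raise a rank error naming the number
of deficient dimensions rather than producing an unstable fit.

### Cortex fitting with 3 slices

A joint 3D MVEE of boundary rings from only three z-planes is ill-posed in
z: a flattened ellipsoid with an inflated equator encloses a stack of rings
in *less* volume than the true near-sphere (for rings of radius ~r at
±2 µm the unconstrained optimum inflates the equator by ~√1.5). The module
default remains the raw joint fit, but the end-to-end pipeline defaults to
`cortex_fit_mode="spherical_prior"`: the widest slice is fitted with a 2D
minimum-area enclosing ellipse and the axial semi-axis is tied to the
in-plane radius mean. This is the appropriate regularization for the
near-spherical mitotic cortex and is what the packaged pipeline and the
verification script use.

## PSF and axial estimation

`simulate_psf` provides either a Gibson–Lanni-style scalar diffraction
integral (pupil integral with the immersion/sample index-mismatch optical
path difference) or, as the tested default, the widefield Gaussian
approximation σ_xy = 0.21 λ/NA, σ_z = 0.66 λ n_i/NA². `fit_psf_gaussians`
fits a 2D Gaussian (independent σ_x ≠ σ_y, in pixels) at the brightest slice
of a bead stack and a 1D Gaussian along z through the brightest column.

Axial inversion uses the normalized axial profile
I = exp(−((z − z_c)/σ)²), inverted as ẑ = z_c + σ·√(−log I). The sign of the
offset (above vs below focus) is not recoverable from a single intensity;
the non-negative branch is returned. Because the spindle is roughly
symmetric about the focal plane, the enclosing-ellipsoid step is insensitive
to this global sign choice. The normalization reference is the maximum
retained intensity inside the mask of the current frame. Depth is estimated
from the single brightest slice per frame.

## Pole refinement

The ellipsoid fit of an intensity point cloud does not land the poles
exactly on the visible spindle tips. `refine_poles` scans the max-projected
spindle mask along the pole-to-pole line at half-pixel steps with
nearest-pixel lookup and snaps the poles to the first and last foreground
pixels; it never extends beyond its scan segment. The tracking pipeline
stretches the scan segment by 20 % about the centroid first (so the
shrink-only scan corrects both over- and undershooting fits) and then nudges
each refined pole outward by half a pixel along the axis: the outermost
foreground pixel *center* of a convex rasterized mask sits on average half a
pixel inside the true boundary, a bias introduced by the float→integer
conversion of the scan. Width/height axes are re-orthogonalized against the
(pixel-snapped) refined length direction, preserving their half-lengths.

## Six-point identity tracking

For each of the three endpoint pairs independently, consecutive frames are
matched with the 2×2 Euclidean distance matrix D(i,j) = d(P_{i,t}, P_{j,t−1})
in physical 3D coordinates; if the cross pairing has the smaller total
distance the labels are swapped and the axis flagged. Exact ties keep the
previous labels. Corrections propagate: the tracker carries a persistent
per-axis swap parity applied to every incoming frame, so a label convention
that flips once is corrected once rather than flagged repeatedly, and the
flag sequence marks toggle events. Greedy per-transition minimization is
globally optimal here because each transition's cost depends only on whether
the pairing crosses, which is verified against exhaustive 2^(T−1)
enumeration in the tests. Frames whose poles fall outside the cortex
ellipsoid (segmentation artifacts) are excluded and logged, never clamped —
clamping would bias the distance series; identity matching then skips to the
last accepted frame.

## Kinematics

With A_t the orthonormal column triad of unit length/width/height
directions, the frame-to-frame rotation is R = A_t A_{t−1}ᵀ (lab frame; a
spindle-frame variant A_{t−1}ᵀ A_t is available and is invariant under
global lab rotations). Euler angles use the ZYX factorization
R = Rz(γ)Ry(β)Rx(α) with standard right-handed factor matrices; extraction
is defined by exact round-trip with this composition (α = atan2(R₃₂, R₃₃),
β = atan2(−R₃₁, √(R₁₁² + R₂₁²)), γ = atan2(R₂₁, R₁₁)). At gimbal lock
(|cos β| < 1e-9) β = ±90° is reported, γ is set to 0, the free angle is
folded into α and the frame is flagged. α is spindle tumbling, β rolling,
γ in-plane rotation.

Displacement between frames (reference point: centroid by default; either
pole by option) is projected onto the previous frame's unit axes, giving
signed longitudinal/equatorial/axial components Δlg, Δeq, Δax whose
absolute fractions satisfy f_lg² + f_eq² + f_ax² = 1 for nonzero motion.
Summaries report per-transition angle series, medians of |α|, |β|, |γ|, the
nearest-rank ECDF quantile (default 0.75), cumulative |angle| series and
median fractions; rates are per frame interval (dt from calibration).

## Classical segmentation

Three conventional pipelines generate masks without a learned model:

- **Chromosomes:** median filter → Otsu two-class threshold → removal of
  8-connected components touching the border → boundary extraction →
  Savitzky–Golay smoothing of the closed contour (treated as two periodic 1D
  signals, default window 15, order 3) → refill.
- **Dye-labeled spindle:** median filter (default 20×20) → adaptive
  local-mean threshold (default block 51 px, with a relative 1e-9 tolerance
  so flat regions do not alias into foreground) → 3×3-disc dilation+erosion →
  convex hull joining the two half-spindles → smoothed boundary →
  direct least-squares ellipse fit.
- **Tubulin spindle (inverse snake):** Gaussian filter → gradient-based
  speed image → morphological geodesic active contour seeded on the
  chromosome-plate mask and driven outward by a positive balloon force, so
  the contour propagates from the spindle center to its outer boundary,
  avoiding cytoplasmic noise. The contour-rigidity/step parameters of a
  classical snake map onto the smoothing/balloon/iterations of this
  implementation.

All classical candidates carry score 1.0 so that `conditional_filter`
(score ≥ threshold — 0.90 by default, matching a 90 % detection threshold —
area window, distance from the canvas border) applies uniformly to
detector-scored and classical masks. `track_centroids` follows one object
through time by bounding-box-centroid nearest neighbor, with ties broken by
higher score then lower index, and gap frames carrying the last centroid.

## Synthetic movies

`generate_movie` renders the acquisition regime end to end: 21 frames,
3 min apart, three z-slices with a 2 µm gap, 512 px frames at 0.06887 µm/px.
The cortex is an axis-aligned ellipsoid with semi-axes (11, 10.5, 10.5) µm
(in-plane eccentricity 0.30) centered on the middle slice; the spindle an
ellipsoid with semi-axes (6, 3.5, 3) µm (length 12 µm, width 7 µm — typical
metaphase dimensions) following a scripted Euler/centroid trajectory, with
a chromosome plate perpendicular to the length axis. Channels: spindle
fluorescence with intensity highest along the pole-to-pole axis and falling
off transversely (microtubule density is concentrated along the length
axis), laterally blurred; a brightfield-like cortex channel (gray field,
dark rim at the slice cross-section); a chromosome-plate channel. Gaussian
noise (σ = 8 counts on a 2000-count signal), optional intensity gradient and
four corruption modes (neighbor object, non-uniform illumination, blur,
intensity drop) are seeded; every frame draws from an independent
`default_rng([seed, frame])` stream, so rendering is order-independent and
bit-reproducible.

Ground truth carries exact per-frame pose, endpoints, pole-cortex distances
(computed with the package's own ray tracer on the true ellipsoids) and
noise-free masks. What the simulator does **not** emulate: photobleaching,
camera-specific noise statistics, out-of-focus haze from structures outside
the slab, neighboring cells, or the real photometric profile of spindles —
so passing tests demonstrate correctness of the geometry/tracking chain, not
segmentation robustness on real microscopy.

## Ray tracing

Lines are transformed into the ellipsoid's principal frame, where
substitution into the centered ellipsoid equation yields
χt² + γt + ζ = 0; the discriminant γ² − 4χζ classifies miss/tangency/two
intersections, with tangency detected on the normalized discriminant at
1e-12 (exact zero is measure-zero in floating point). Roots use the
numerically stable quadratic formula. Pole-to-cortex distances extend the
pole-to-pole line; the hit on each pole's outward side gives
d_i = ‖pole_i − hit_i‖.

## Verification quantities and problem sizes

`scripts/acceptance.py` recomputes, from scratch at the given seed: MVEE
volume agreement with the SLSQP oracle and containment slack over 200 random
clouds (n ≤ 100); ray-tracing root agreement with a dense scan over 500
random line/ellipsoid pairs; axial inversion error over a 10⁴-point grid;
Euler round-trip error over 1000 random triples (|β| ≤ 85°); swap-detection
and labeling-optimality rates over 100 scrambled 21-frame tracks plus 20
exhaustively enumerable 8-frame tracks; pole-refinement exactness over
2–10 px overshoots; a full synthetic end-to-end run (default regime,
γ = 5°/frame script with centroid drift) reporting the median |γ| error,
maximum pole-cortex distance error and fraction-norm deviation; metric
oracles (50 IoU pairs, the 3-prediction AP sweep, a rendered perpendicular
metaphase scene); and the Stage-3 filter against an enumerated oracle.
These sizes keep the script under a minute on one CPU while exercising
every stage.

## Known limitations

- With three z-slices, out-of-plane (α/β) rotation beyond a few degrees per
  frame moves the poles between slices where the mask union under-covers the
  projected spindle; pole positions and distances then degrade (the in-plane
  γ component remains accurate). This is a data limitation of the sparse
  axial regime, not of the algorithms.
- The spindle width/height readouts from a single-slice intensity cloud
  reflect the bright core, not the full spindle envelope; their *directions*
  (used for tracking and angles) are reliable, their magnitudes are not.
- The axial sign ambiguity of the PSF inversion makes absolute spindle tilt
  unobservable from one slice; tilt enters only through cross-slice
  information.
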