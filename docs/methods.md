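# Methods

## The measurement model

Two cameras with telecentric lenses observe a common volume while a
projector throws a sequence of varying patterns onto the surface. A
telecentric lens realizes (to first order) a parallel projection: with
magnification `M` (dimensionless) and sensor pixel pitch `pp` (mm/px),
a world point `X` maps to centered pixel coordinates

```
(u, v) = ( (M_x/pp) · (R X + t)_x ,  (M_y/pp) · (R X + t)_y )
```

independent of the depth coordinate of `R X + t`. There is no principal
point — the intrinsic matrix is `diag(M_x/pp, M_y/pp, 1)` — and pixel
(0, 0) is defined to be the image center. All internal lengths are mm
(the measurement volume is ~10 mm); intrinsic entries quoted in px/m are
converted on input. Anisotropic magnification (`M_x ≠ M_y`) is
supported; calibrated systems commonly show a fraction of a percent of
anisotropy. Lens distortion is not modeled: for metrology-grade
telecentric optics the residual distortion is far below the other error
sources at this scale, and modeling it would raise the calibration
burden considerably.

Back-projection of a pixel is a world-space *line* with the camera's
viewing direction `Rᵀ ẑ` (all pixels share it — the rays are parallel).
A correspondence pair is triangulated as the midpoint of the common
perpendicular between the two rays; the residual ray–ray distance
("gap") is kept as a per-point quality diagnostic next to the
correlation score, but plays no role in default filtering.

### Magnification convention

The implementation stores the magnification `M` such that `K = M/pp`.
For the reference hardware this gives `M = 0.69` (4 µm of object space
per 2.74 µm pixel). Vendor documentation sometimes quotes an "effective
magnification" in the reciprocal convention (≈1.46 for this lens); only
the ratio `M/pp` ever enters the math.

## Temporal correlation matching

Each surface point acquires a temporal intensity signature from the
pattern sequence; two pixels viewing the same point record the same
signature up to gain, offset and noise. The match score is the zero-mean
normalized cross-correlation (NCC) across time — no spatial windows, so
the method needs no local texture assumptions and reaches single-pixel
granularity.

Search proceeds in two phases: a full-image search at a coarse stride
(default 8) yields confident seed pairs from which the affine
fundamental matrix is estimated; a dense pass (default stride 2) then
searches only a ±2 px band around each epipolar line.

Numerical and robustness choices:

* **Subpixel refinement** is an axis-separable three-point parabola on
  the 3×3 NCC neighborhood of the integer peak, clamped to ±0.5 px.  In
  a convergence study on band-limited random patterns the separable
  form reached ~0.027 px mean absolute error for a 0.3 px shift at 100
  frames, versus ~0.047 px for the full 9-point least-squares
  paraboloid — the cross term mostly injects the local autocorrelation
  asymmetry of the pattern realization into the estimate. Peaks on the
  border of the search region are discarded, not refined; a neighbor
  that carries no valid correlation (e.g. an unlit pixel next to a thin
  bright line) suppresses refinement along that axis only.
* **Perfect peaks**: a score within 1e-5 of 1.0 (the single-precision
  accumulation limit) identifies an exact match; refinement could only
  move away from it and is skipped. This makes constructed integer
  shifts recover exactly.
* **Modulation floor** (default 0.05 of full scale): pixels whose
  temporal standard deviation is below the floor — unlit background
  whose only variation is sensor noise — are excluded. Without it, the
  maximum of thousands of random correlations reaches ≈0.35 and
  pollutes lax-threshold reconstructions.
* **Left-right consistency** (optional in the matcher, enabled in the
  pipeline's dense phase): a pair is kept only if the reverse match of
  its camera-2 peak lands within 1 px of the starting pixel. This
  removes half-occluded rim pixels that have no true partner yet
  correlate moderately with a neighbor.
* Correlation thresholds: calibration uses only pairs scoring ≥ 0.9
  (least-squares estimation is outlier-sensitive); reconstruction
  defaults to ≥ 0.3, the regime for difficult scattering surfaces.
* **Pattern statistics**: frames are white noise low-pass filtered at a
  separable cutoff of 0.12 cycles/px and rescaled to [0, 1]. The cutoff
  balances subpixel interpolability (smoother is better) against
  temporal distinctiveness and was fixed by the same convergence study;
  a cutoff of 0.5 reproduces unfiltered white noise exactly.

## Extrinsic calibration and the telecentric correction

The affine fundamental matrix `F` (zero upper-left 2×2 block) is
estimated by the gold-standard affine method: subtract centroids, take
the smallest right-singular direction of the centered n×4 data matrix
as the linear coefficients, recover the constant from the centroids.
This is the total-least-squares optimum; a single isotropic scale is
applied for conditioning (it does not move the minimizer).

Feeding `E = K₂ᵀ F K₁` through the standard essential-matrix
decomposition — what any pinhole-oriented library does — produces two
rotations and a sign-ambiguous translation. For a telecentric pair this
candidate set is *structurally wrong*: in metric coordinates the affine
epipolar constraint fixes the epipolar directions in both images and
the in-plane baseline component, but not the turn angle θ about the
epipolar axis. Varying θ rescales reconstructed depth while leaving
every image observation unchanged (the bas-relief ambiguity of parallel
projection), so the rotations consistent with a given `F` form a
one-parameter family

```
R(θ) = Rz(α₂) · Ry(θ) · Rz(α₁),
```

with α₁, α₂ read off `F` and the intrinsics. The decomposition's two
candidates are merely two points picked out of (a projection of) this
geometry — typically one near the identity and one near a half-turn —
and neither reconstructs correctly. An internal consistency check falls
out of the same algebra: the metric coefficient norms of the two images
must be equal (both equal sin θ up to the common scale); their relative
mismatch is reported as a diagnostic.

`correct_extrinsics` recovers θ with a reference object of known shape:
for each trial angle it triangulates the calibration correspondences
and fits a sphere of the known radius; the residual standard deviation
is minimized over a grid (default 256 angles, ±89°) followed by bounded
parabolic refinement. Two symmetric minima always exist — the solution
and its depth-reversed (Necker) twin, which fits the sphere equally
well. The twin is rejected by a physical convexity rule: a real opaque
sphere is seen from outside, so the fitted center must lie beyond the
surface points along the first camera's viewing direction. On
noise-free synthetic data the recovered rotation matches ground truth
to < 1e-3 degrees; in the full noisy pipeline to < 0.1°.

The reference must be curved. A plane cannot pin θ down: triangulation
is linear in the correspondence coordinates, so a planar scene yields a
planar cloud at *every* candidate, and the leading-order noise
amplification is even equal for the twisted pair (sin θ = sin(π−θ)).
Plane references remain useful for exposing near-degenerate
(near-parallel-ray) candidates, whose noise amplification is
catastrophic.

### The deviation-from-identity heuristic

Practitioners facing the two decomposition candidates are often told:
the rotation that deviates more from the identity is (usually) the
meaningful one. `select_by_identity_rule` implements this with the
Frobenius-distance margin as a confidence diagnostic and refuses to
decide when the margin is negligible. The rule's validity envelope is
narrow, and the package measures rather than assumes it:

* Its natural habitat is the rig class in which the second camera is
  mounted head-down (rotated half a turn about its optical axis — the
  common arrangement when two cameras face the volume from opposite
  sides; `default_rig(flip_camera2=True)`). There the true relative
  rotation is itself a near half-turn — the farthest a rotation can be
  from the identity — and the rule is correct whenever its margin is
  non-negligible.
* The symmetric converging rig sits on a knife edge: its baseline is
  almost perpendicular to the relative-rotation axis, which drives the
  spurious candidate's identity-deviation toward the same maximal value
  2√2 and the margin toward zero, where small cyclotorsion decides the
  comparison either way. Measured over randomized head-down rigs the
  rule agrees with reference-based selection in only ~60 % of trials —
  the corresponding acceptance test is deliberately left failing as a
  quantitative record of this envelope.
* For rigs without the head-down mount the rule inverts outright: the
  true rotation (≈ the stereo angle from identity) is always the
  *nearer* candidate.

Reference-based selection is therefore the pipeline default, and the
command-line `calibrate` refuses to run on the heuristic alone.

### Baseline, sign and scale ambiguities

For parallel-ray cameras the baseline magnitude only translates the
reconstruction; both signs of `t` give congruent clouds with identical
residual statistics (verified to 1e-9 mm). Reconstructions are produced
in the first camera's frame with the in-plane baseline component taken
from the epipolar constant, and made metric by `estimate_scale`: the
cloud of a feature grid of known pitch is projected onto its best-fit
plane, the grid orientation found by maximizing 1-D projection
concentration, features clustered along both grid axes (sub-clusters
closer than half the dominant pitch are merged — discrete pixel
sampling can split a thin line into a doublet), cluster centers refined
from the raw points within a tight window, and the median
nearest-neighbor spacing compared with the true pitch. Synthetic grids
with an injected global scale recover the factor to < 0.5 %.

## The synthetic rig

The renderer replaces the instrument: parallel viewing rays are
intersected analytically with the scene (plane with optional i.i.d.
Gaussian micro-roughness along the normal; sphere, with the
camera-facing intersection chosen; line grid with bright lines of
albedo 0.9 on a 0.05 background), the surface point is carried along
the projector direction onto the pattern plane, sampled bilinearly per
frame, and Gaussian intensity noise is added and clipped to [0, 1].
Geometry is computed once per camera; only the pattern sample varies
over the sequence. Misses record the background intensity. Per-pixel
hit masks and true 3D point maps are returned, so every downstream
stage can be checked against exact ground truth.

The default desk-scale configuration keeps the full 11 mm field of view
at 256×256 px by scaling the sensor pitch accordingly (all geometry is
scale-free); the full-resolution sensor configuration (2848², 2.74 µm
pitch, M = 0.69, 38.5° stereo angle, 120 mm working distance) is the
`default_rig` default. Camera centers are placed physically on the
optical axes — telecentric projection is insensitive to this, but the
pose translations then represent the real ~8 cm baseline rather than an
arbitrary convention, which matters to everything built on the
essential matrix.

What the simulator does *not* emulate: defocus, vignetting, speckle,
projector depth-of-field, cast shadows, inter-reflections, color, and
surface BRDF effects — scenes are single convex Lambertian surfaces
viewed front-on. Passing tests therefore demonstrate the correctness of
the geometry, matching and statistics pipeline, not robustness to the
photometric pathologies of difficult real specimens.

## Validation statistics

Plane fits are total least squares (smallest-eigenvalue direction of
the centered covariance); sphere fits use an algebraic linear
initialization refined by Gauss–Newton on the geometric distance, with
an optional fixed radius (center-only refinement, initialized on both
sides of the cap's plane and keeping the better optimum). Reported
"standard deviation" is the population standard deviation of the signed
residuals; at the typical 10⁴–10⁶ points the sample/population
distinction is irrelevant but the convention is fixed. Histograms use a
fixed bin width defaulting to std/10.

`central_patch` keeps the innermost fraction of points ranked by radial
distance from the viewing axis through the centroid — the low-slope
region where triangulation noise is smallest; residual std on the
central half of a noisy cap is never larger than on the full cap. The
fraction is a free parameter (a commonly used value for cap analyses is
0.485); an axis-aligned crop box removes support structures such as a
holding platform. Polyline length is the plain sum of segment lengths;
its 2-D projection is never longer than the 3-D curve, which is the
whole argument for measuring curved anatomy in 3-D.

## Error scaling

Depth precision follows σ_z ≈ σ_px · w / sin θ for stereo angle θ and
world pixel size w (verified: the 20° vs 40° depth-noise ratio matches
sin 40°/sin 20° within a few percent). Larger angles buy axial
precision at the cost of overlap and occlusion; ~40° is a practical
compromise. The end-to-end synthetic sphere experiment (2 % intensity
noise, threshold 0.3) yields ~0.07 px effective correspondence noise
and a 4 µm deviation from sphere form, consistent with this propagation
within a factor of two.

## Problem sizes

The test and acceptance suites run the full pipeline at 256×256 px with
100 frames (≈2×10³–10⁴ retained points), statistical checks at 10⁵
samples, and ensembles of 20–100 randomized rigs; the complete suite
executes in about a minute on one core. All randomness is seeded;
renders, matches and reconstructions are bit-reproducible, and the
command-line chain produces byte-identical cloud files across runs.

## Known limitations

* Single-view reconstructions only; multi-view registration into full
  360° models is out of scope.
* The turn-angle correction requires a curved reference of known size
  in the shared field of view; with only planar references the depth
  scale remains free.
* The depth-reversal tie-break assumes an opaque convex reference seen
  from outside.
* Matching assumes a static scene across the pattern sequence and
  near-equal exposure between cameras (NCC removes gain and offset but
  not saturation or motion).
* The epipolar-band search assumes epipolar lines closer to horizontal
  than vertical in image 2 (rotate inputs by 90° otherwise).
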