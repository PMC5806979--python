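# Methods

## Coordinate conventions and units

Pixel coordinates have their origin at the top-left corner, x rightward, y
downward, pixel centers at integer coordinates. Camera frames are x right,
y down, z away from the camera. All lengths are millimetres; timestamps are
`frame_index / fps` with 30 fps by default. Range images and everything
derived from them live in the **left rectified camera frame**, which is the
single world frame of the downstream analysis.

## Camera model

The Tsai model is used throughout: rigid transform `p = R X + T`,
perspective division `(Xu, Yu) = f·(x, y)/z`, first-order radial distortion,
and pixel mapping with pitch `(dx, dy)`, scale `sx`, and center `(cx, cy)`.
Distortion follows the classic distorted-to-undistorted form
`Xu = Xd (1 + κ₁ r_d²)`, so undistortion is closed-form while projection
inverts the cubic `r_d + κ₁ r_d³ = r_u` by Newton iteration (tolerance
1e-13, max 50 sweeps; non-convergence raises rather than returning NaN).
Only κ₁ is modelled — higher-order and tangential terms are out of scope.

Calibration accepts a YAML/JSON config or a correspondence table
(CSV `X,Y,Z,u,v`). Estimation is two-stage: the radial alignment constraint
gives R, Tx, Ty linearly (both the planar closed form, ≥ 7 points, and the
non-coplanar form, ≥ 11 points, are implemented, with sign candidates
disambiguated by reprojection cost); f and Tz are initialized linearly; and
all of (R, T, f, κ₁) are refined by Levenberg–Marquardt on the reprojection
residual with `cx, cy, sx, dx, dy` held fixed, per the classic formulation.
On noise-free synthetic targets this recovers parameters to machine
precision; the guaranteed tolerances (f within 0.1%, κ₁ within 1%, ‖T‖
within 0.01 mm) are deliberately loose.

Rectification uses the standard shared-orientation construction: new x-axis
along the baseline, y-axis orthogonal to baseline and old left optical axis.
A fronto-parallel rig with baseline along +x rectifies to the identity. Both
rectified views share the left camera's intrinsics with κ₁ = 0; warping
samples the original distorted images bilinearly.

## Scanline matching

The dissimilarity between left pixel x_l and right pixel x_r is the
symmetric sampling-insensitive measure: the smaller of the two one-sided
minimum distances between one pixel's intensity and the other scanline
linearly interpolated over ± half a pixel, evaluated in closed form from the
interval extremes. Scanline borders are handled by clamping the missing
neighbor inside the kernel; the public `pixel_dissimilarity` raises at
borders instead.

Each row is solved to global optimality by dynamic programming for the
objective `Σ dissimilarity + N_occ·κ_occ − N_match·κ_r` under the ordering
constraint, where an occlusion is a *maximal run* of unmatched pixels in one
image between two matches (penalized once), consecutive matches must be
contiguous in at least one image, and unmatched pixels before the first and
after the last match are free. Defaults κ_occ = 25 and κ_r = 5 (0–255
intensity scale) follow the published constants of the pixel-to-pixel
technique. Disparity is left-referenced (`x_right = x_left − d`, d ≥ 0) and
integer-valued: subpixel refinement is out of scope, so depth is quantized
by `Δz ≈ z²·dx/(f·B)` per disparity step. The optional reliability
propagation between scanlines of the original technique is not implemented;
the pure DP is the core. A disparity search band (`min_disparity`,
`max_disparity`) and a row band restrict work to the plausible depth range
and the region of interest; both default to the full range. The DP kernel is
compiled with numba; a brute-force enumeration oracle verifies optimality on
small rows in the tests.

Occluded pixels are masked invalid and never interpolated. Hole handling is
deferred to grid sampling, with explicit rules below.

## Virtual grid and center of gravity

The ROI is a convex quadrangle given by four pixel corners on the reference
(rest) frame; input corners in any order are canonicalized TL, TR, BR, BL by
angular sort around their centroid. Equal subdivision places node (i, j) at
the bilinear blend of the corners at parameters (i/n, j/n); n = 5 gives the
standard 36 intersections.

The grid is defined **once in image coordinates and held fixed**; each
frame's 3D samples are read from that frame's range image at the same pixel
positions. Consequence: the trajectory measures apparent motion of the
surface along fixed viewing rays, not material-point motion — when the
surface translates by δ·u, the intersection with a fixed ray moves along the
ray by δ(u·n̂)/(r̂·n̂). Ground truth for end-to-end validation is therefore
generated with exactly the same fixed-ray semantics.

Node sampling is bilinear over the valid pixels of the 2×2 neighborhood with
renormalized weights; a node with fewer than two valid neighbors is invalid.
Invalid node samples are filled from the same node's nearest valid frame in
time; a node valid in no frame is dropped from all frames (logged), shrinking
the PCA dimensionality, so no geometry is ever invented. The center of
gravity is the unweighted mean of valid nodes; the motion summary is the
maximum Euclidean displacement of the CoG from the rest frame (frame 0 by
default, overridable).

## Motion statistics

The observation matrix is T × 3N (node-major x, y, z), rest frame
subtracted. PCA is computed by SVD of the column-centered matrix;
eigenvalues are score variances (divisor T − 1). Requesting more components
than the achievable rank truncates with a warning. Eigenvector sign is fixed
by orienting each loading so the score of the frame with the largest
rest-relative displacement is non-negative; this removes the sign ambiguity
that otherwise breaks pooling scores across subjects. PCA is fit per subject
(each recording its own modes), and group-level analyses pool the per-frame
(PCS1, PCS2) pairs; `fit_pca` itself is agnostic and can be applied to any
stacked matrix. Mode shapes for visualization are `mean + score·loading`
(plus the rest configuration), exported at scores {−2 SD, 0, +2 SD}.

Mann–Whitney U is two-sided throughout (no hard-coded α); the exact null is
used when the pooled sample is tie-free and n₁+n₂ ≤ 25, otherwise the normal
approximation with tie and continuity corrections (computation delegated to
scipy). If all values are identical the test is degenerate and returns p = 1
with a warning.

The discriminant is the classical two-class pooled-covariance linear rule
with equal priors, computed in closed form; a near-singular pooled
covariance (condition number > 1e12 — e.g. two points per class) is
regularized by adding 1e-8·trace/p to the diagonal, logged. Resubstitution
accuracy is reported as the primary figure (consistent with classical
practice), with leave-one-subject-out accuracy alongside because frame-level
resubstitution is optimistic. Note that under the null (no group difference)
leave-one-subject-out is *pessimistic*: the held-out subject always belongs
to the minority class of the training split, so its frames are
systematically classified the other way.

## Synthetic scenes: what they emulate and what they do not

The generator emulates the measurement situation: a smooth 22 × 22 mm patch
centered at 40 mm depth (inside the validated 20–60 mm working envelope,
warning outside), carrying a lattice texture — the physical projected
pattern is modelled as *surface-attached* texture, since the matcher uses
the pattern only as texture and attachment gives exact ground-truth
correspondence. The default motion is one mode in the posterior-upper
direction (0, −sin45°, −cos45°) in the camera frame with peak amplitude
4.7 mm (the center of the reported per-group shift magnitudes), a smoothstep
rise–hold–fall envelope over 30 frames at 30 fps with envelope(0) = 0, and a
smooth `sin(πs)·sin(πt)` spatial bump (uniform weighting available).
Rendering is per-pixel ray/parametric-surface intersection (vectorized
Newton, residual < 1e-10 mm), through the full distortion model, with seeded
Gaussian pixel noise (sd 2.0 on the 0–255 scale) added last; two seeds
differ only in noise.

The canonical rig is synthetic: two 640 × 480 cameras, f = 6 mm, 10 µm
pitch, κ₁ = 5e-4, baseline 12 mm with 1.5° toe-in. It was chosen so the
depth quantization from integer disparity is ≈ 0.22 mm at 40 mm — small
against the 0.3 mm end-to-end tolerance — while keeping the deforming patch
inside both views; it does not model the millimetre-scale optics of a real
endoscope tip.

The two-mode scene adds a weaker second mode. Because "posterior-upper" and
"upper" are 45° apart and PCA can only recover orthogonal modes, the
secondary direction is the upper direction with its posterior-upper
component removed, (0, −sin45°, +sin45°); the temporal profiles sin²(πt/T)
and sin²(2πt/T) are exactly orthogonal discrete harmonics with equal
variance, so the injected eigenvalue ratio equals the squared amplitude
ratio (4:1 at default amplitudes 4:2).

The cohort generator works at trajectory level (no rendering): each subject
draws a peak shift from their group mean — 4.74 mm males, 4.66 mm females —
with 0.8 mm between-subject SD (chosen as a plausible spread; none is
reported), a posterior-upper direction jittered by 5° SD, uniform spatial
weighting so the drawn amplitude *is* the subject's true maximum CoG shift,
and 0.05 mm isotropic node measurement noise (consistent with the reported
≈ 0.2 mm standard error over 30 frames).

What passing tests therefore show: the geometry, matching, sampling and
statistics chain is correct to its stated tolerances under realistic imaging
noise and quantization. What they do not show: robustness to specularities,
wet-mucosa texture, breathing motion, fixation drift, interlacing artifacts
of real analog video, or physiological muscle mechanics — none of which the
renderer models.

## Problem sizes and numerical choices

End-to-end validation runs the canonical scene (30 frames, 640 × 480) for 20
seeds, matching only the ROI row band and the scene's disparity band — both
standard practice and the package's own default experiment configuration.
Calibration refinement uses LM with ftol/xtol 1e-14 and multi-start over
radial-alignment sign candidates. PCA tolerances: rank cutoff at 1e-12 of
the leading singular value; loading orthonormality holds to 1e-9. Degenerate
inputs raise typed exceptions (`velogrid.errors`) rather than propagating
NaN. The scanline DP and its enumeration oracle agree to 1e-6 in cost;
disparities are exact integers.

## Known limitations

Integer disparity bounds depth resolution; no temporal smoothing of range
images; the grid is not a tissue-tracking method (fixed-pixel semantics, see
above); the Mann–Whitney exact path refuses ties (falls back to the
corrected normal approximation); the discriminant assumes two classes with
equal priors; composite-video packing supports side-by-side and over-under
layouts only.
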