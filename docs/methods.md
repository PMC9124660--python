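# Methods

## Model and estimation pipeline

Fetoscopic image registration is posed as estimating a planar affine
transform between consecutive frames. The affine model (6 dof: scale,
shear, rotation, translation) is deliberately preferred over a projective
one: when hundreds of pairwise transforms are accumulated, affine chains are
more stable and less prone to divergent shrinking or enlargement of the
mosaic.

Per frame pair the pipeline is:

1. **Dense flow.** Either the built-in pyramidal Lucas–Kanade estimator or
   an imported flow raster. Flow convention: a pixel `(x, y)` in frame *i*
   maps to `(x+u, y+v)` in frame *i+1*.
2. **Correspondences.** Valid flow pixels inside the circular field-of-view
   mask are sampled on a stride grid (default stride 2, ≈25 % of pixels, to
   bound RANSAC/LM cost) and converted into explicit point pairs. Masked-out
   pixels are *excluded* rather than zeroed: a correspondence forced to
   (0, 0) would be a gross outlier, not a removal. Destination points may
   leave the field of view; only the source side is constrained.
3. **RANSAC.** Minimal 3-point affine solves (rejecting samples whose source
   triangle area is below 1e-8 px²) vote with the inlier rule
   `residual ≤ threshold` (default 6 px; the boundary counts as inlier).
   Iterations adapt as `log(1−confidence)/log(1−w³)` with `w` the best
   inlier ratio so far, capped at 2000, confidence 0.99. The winner is refit
   by least squares on its consensus set. Per-pair RNG streams are derived
   from `(master seed, pair index)`, so runs are reproducible and pairs
   independent.
4. **Levenberg–Marquardt.** Damped normal equations on the squared
   re-projection error; steps are accepted only if the cost decreases
   (multiplicative λ adaptation, start 1e-3, ÷10 on accept, ×10 on reject),
   so the accepted-step cost sequence is non-increasing. Because the model
   is linear in its six parameters the cost is quadratic and LM converges to
   the closed-form least-squares minimizer — which the tests exploit as an
   oracle. Termination: step norm < 1e-10 or 100 steps.
5. **Robust-regression alternative.** A single-stage fit with the soft-L1
   loss `ρ(z) = 2(√(1+z)−1)` (scipy `least_squares`, `f_scale` defaulting to
   the RANSAC threshold so the two robust schemes share an influence scale),
   initialized from the plain least-squares solution. The inlier mask is
   re-derived post hoc with the 6 px rule for reporting only.

**Transform direction.** The stored pairwise transform maps frame *i+1*
coordinates into frame *i* (the direction implied by the re-projection
residual definition). Chaining toward an earlier reference frame is then
plain left multiplication; the opposite direction uses the exact inverse.

## Mosaicking

The reference frame defaults to the middle index ⌊n/2⌋ (it tends to sit near
the center of the mosaic). Absolute transforms are composed outward from the
reference in both directions. The canvas covers the union of all transformed
field-of-view bounding boxes plus a 2 px margin. Frames are inverse-warped
with bilinear interpolation; validity is the warped mask footprint.

Blending modes:

- **feather** (default): distance-transform-weighted average. Deterministic,
  exact for constant overlap, and used for acceptance runs.
- **multiband**: a self-contained Burt–Adelson-style blender — Laplacian
  pyramids combined level-wise with Gaussian-smoothed normalized weights,
  renormalized per level (smoothed weight sums drift below one near coverage
  edges), with nearest-valid fill outside each footprint so the zero
  background does not bleed into boundary coefficients. It makes no claim of
  matching any external blender bit-wise.

On a registration failure the chain policy is configurable: `stop` (truncate,
default) or `identity-bridge` (insert identity, flag the pair).

## Drift metric

With no ground truth for in vivo footage, accumulated drift is quantified as
SSIM between frame *i* and frame *i+t* warped through the composition of the
*t* intervening pairwise transforms, *t* = 1..N, default N=5. SSIM uses the
standard parameterization (11×11 Gaussian window, σ=1.5, k₁=0.01, k₂=0.03,
dynamic range 1, grayscale via Rec. 601 luma) and is averaged over windows
fully inside the warped overlap of the circular masks — including the black
surround would inflate similarity. Per-offset distributions are summarized
as boxplots: median, Q1/Q3 (linear-interpolation quantiles), whiskers at the
most extreme data within 1.5·IQR of the quartiles, the rest listed as
outliers. The *t*=1 slice is the consecutive-registration time plot; a sharp
minimum marks a broken pair.

## Built-in Lucas–Kanade flow

Coarse-to-fine (factor-2 pyramid with Gaussian pre-smoothing σ=1, default 3
levels), per-pixel windowed normal equations (uniform 21×21 window, 5
iterations per level, warping the target by the running flow between
iterations, per-iteration update clamped to the window radius). Pixels whose
structure tensor's smallest eigenvalue falls below 1e-4 (on [0, 1]
intensities) are invalid — the aperture problem — as are pixels whose warp
leaves the frame.

One bias matters in this application: the circular field-of-view rim is
*static* in frame coordinates while the scene moves, so LK windows
overlapping the rim are dragged toward zero motion. Those residuals (bounded
by the camera step, typically < 6 px) sit *below* the RANSAC threshold and
cannot be rejected as outliers. Registration with the built-in backend
therefore excludes a rim annulus whose width equals the full pyramid spatial
support, `(window//2)·2^(levels−1)` = 40 px at defaults; imported flow is
used to the full mask. On simulated sequences this reduces the maximum
corner error of a pairwise estimate from ≈0.94 px to ≈0.33 px.

## Simulator: the stated world

Defaults describe a desk-scale but structurally faithful fetoscopy scene:

- **Texture** (1024², RGB): reddish base (0.58, 0.30, 0.26) with
  low-frequency luminance modulation and 8 dark curvilinear vessels
  (AR(1)-filtered heading random walks, widths 3–9 px).
- **Motion**: AR(1)-smoothed (coefficient 0.8) per-step similarity
  transforms, caps 5 px translation and 2° rotation per step, scale fixed;
  50 frames of 320² by default. The trajectory is validated against the
  texture bounds.
- **Sensor noise**: additive Gaussian, σ=0.002 on [0, 1] (≈0.5 LSB of an
  8-bit sensor). This value is pinned by the requirement that the drift
  metric under *ground-truth* transforms on artifact-free renders scores a
  median SSIM ≥ 0.99 at t=1 (measured floors: 0.946 at σ=0.01, 0.986 at
  σ=0.005, 0.997 at σ=0.002): the metric's noise floor must not mask
  registration error.
- **Field of view**: centred circle of radius 0.45·frame side, with radial
  vignetting (strength 0.4) and black surround.
- **Particles**: blob radius 2–6 px, independent random-walk steps of
  10–25 px/frame (fast-floating debris, clearly inconsistent with the ≤5 px
  camera steps — the property RANSAC must exploit); particle count derives
  from the target covered fraction via the Poisson coverage model
  `n = −A·ln(1−d)/ā` so the labelled fraction honors the configured density.
- **Speculars**: 3 near-saturated blobs (radius 4–10 px) anchored to the
  camera frame, modeling light-source reflections; their apparent motion is
  zero, so at small camera steps their flow residual can legitimately fall
  under the 6 px threshold.

Ground-truth flow stores the *background* motion everywhere and labels
artifact pixels; `corrupted_flow` substitutes each artifact pixel's own
apparent motion, giving both a clean and a corrupted flow-oracle regime.

**What a green test does not establish.** The simulator has no fetal
anatomy, no amniotic-fluid optics, no photometric drift, no motion blur, no
rolling shutter, and its motion is exactly affine — so recovery results
bound algorithmic error only, not performance on in vivo footage, and the
published in vivo similarity tables are out of reach by construction (they
require the clinical dataset and GPU deep-flow inference).

## Numerical choices and degenerate inputs

- Transforms are 2×3 float64 matrices; composition/inversion go through the
  homogeneous 3×3 form. Inversion of a linear part with |det| < 1e-12 raises
  a degenerate-transform error.
- The two coordinate blocks of the affine least-squares problem decouple
  into two 3-parameter solves sharing one design matrix; rank deficiency
  (collinear sources) raises a degenerate error.
- SSIM of a frame with itself is exactly 1.0; constant images reduce to the
  closed-form luminance term, used as an oracle in tests.
- Flow files: raw float32 planes (u, v[, validity]) with a JSON sidecar, or
  the common two-channel `.flo` binary layout (magic tag, width, height,
  interleaved u, v). Malformed files raise explicit errors.
- All stochastic components (texture, trajectory, artifacts, RANSAC) are
  seeded; reruns are byte-identical.

## Known limitations

- No global optimization or loop closure: drift accumulates without bound in
  long sequences; the drift metric quantifies but does not correct it.
- The rim-annulus exclusion assumes a circular mask; arbitrary raster masks
  fall back to full-mask sampling with the bias unmitigated.
- The multiband blender is a generic Laplacian-pyramid scheme, not a
  re-implementation of any specific external tool.
- Video-container input requires an imageio backend with video support;
  environments without one must use frame directories.
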