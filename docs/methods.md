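# Methods

## Model

A stack of $n$ grayscale images of one anatomy, each $w \times h$ with
intensities in $[0,1]$, is vectorized into $A \in \mathbb{R}^{m\times n}$,
$m = wh$.  Three assumptions drive the decomposition:

1. **Low-rank normal appearance.**  Aligned, lesion-free images of the
   same anatomy are close to linearly dependent, so the healthy component
   $L$ has small nuclear norm.
2. **Structured-sparse pathology.**  A lesion occupies a contiguous
   patch in one image.  The penalty
   $\Omega(S) = \sum_i \sum_{g\in G} w_{g,i}\,\lVert\mathrm{mat}(S_i)_g\rVert_\infty$
   over all 3×3 unit-stride windows $G$ charges a whole window for its
   largest entry, so support grows in patches.  The window norm is the
   maximum *absolute* value: a signed maximum would not be a norm, and
   the penalty must also catch hypointense outliers.
3. **Small affine misalignment.**  Each image is observed through an
   unknown affine map $\tau_i$ (6 parameters: full 2×2 linear part plus
   translation); the constraint is $A\circ\tau = L + S$.

The uniform penalty is $w_{g,i} \equiv \lambda$ with
$\lambda = 1/\sqrt{\max(m,n)}$ by default (the classical robust-PCA
scaling, applied in the column-normalized space).  The adaptive variant
replaces $\lambda$ with the per-pixel map $\lambda(1-P)$, $P$ a tumor
probability in $[0,1]$; because $\Omega$ aggregates per group while $P$
is per pixel, the group weight is the mean of its nine pixel weights —
the simplest lift that is exact for constant $P$ and vanishes where
$P\equiv 1$.

## Optimization

The warp makes the problem nonconvex, so an outer loop linearizes it
RASL-style at the current $\tau$:
$A\circ(\tau+\Delta\tau) \approx A\circ\tau + \sum_i J_i\,\Delta\tau_i\,\epsilon_i^T$,
with $J_i$ the Jacobian of the vectorized warped image with respect to
$\tau_i$.  Each linearized convex problem is solved by an inexact
augmented Lagrangian with penalty $\mu$ and multiplier $Y$, alternating:

* **L-step** — singular-value thresholding of
  $A\circ\tau + J\Delta\tau - S + Y/\mu$ at level $1/\mu$ (thin SVD; at
  these sizes, $m \le $ a few thousand and $n$ a few dozen, a full thin
  SVD per iteration is cheap).
* **S-step** — the proximal operator of $\Omega$, solved through its
  dual: writing the window norm via its $\ell_1$ dual gives a smooth
  quadratic over a product of $\ell_1$ balls (one per group, radius
  $w_{g,i}$), maximized by FISTA with adaptive restart.  Each iteration
  is one vectorized gather / $\ell_1$-ball projection (sort-based) /
  scatter over all groups and columns; the 9 "colors" of 3×3 windows
  (top-left corner mod 3) partition the groups into collision-free
  scatter batches.  Iteration stops at a per-column duality gap below
  `prox_tol`·‖column‖ (default 1e-6).  Cyclic block-coordinate ascent on
  the same dual was tried first and stalls near the optimum when several
  pixels tie for a window maximum; the accelerated gradient does not.
* **Δτ-step** — closed-form least squares,
  $\Delta\tau_i = J_i^{+}(L + S - A\circ\tau - Y/\mu)_i$, with the
  pseudoinverses precomputed once per linearization.
* **Multiplier** — $Y \leftarrow Y + \mu h$, $\mu \leftarrow \min(\rho\mu, \mu_{\max})$
  with $h$ the linearized constraint residual, $\mu_0 = 1.25/\sigma_1$,
  $\rho = 1.25$, $\mu_{\max} = 10^7\mu_0$, and the standard warm start
  $Y^0 = A\circ\tau / \max(\sigma_1, \lVert\cdot\rVert_\infty/\lambda)$.

The inner loop stops at relative residual
$\lVert h\rVert_F / \lVert A\circ\tau\rVert_F \le$ `tol_inner` (default
1e-7, cap 200 iterations); then $\tau \leftarrow \tau + \Delta\tau$ and
the outer loop re-linearizes, stopping when $\lVert\Delta\tau\rVert_F \le$
`tol_outer` (default 1e-4) or after `outer_max` = 10 linearizations.
$\tau$ is initialized at the identity; the phantom's jitter (a few pixels
and degrees) is well inside the linearization's capture range.

Three performance choices matter and do not change the optimum:

* **Warm restarts.**  The prox dual variables persist across all inner
  and outer iterations; when $\mu$ changes they are rescaled radially
  with a cap at the ball radius (unsaturated blocks scale with $\mu$,
  saturated ones stay pinned), and converged columns are frozen out of
  the FISTA iteration.
* **Inexact inner solves.**  Early in the ALM the prox is solved to a
  gap proportional to the current constraint residual (never looser than
  1e-3, tightening to `prox_tol`); the final iterations therefore use the
  full tolerance.  This is the usual inexact-ALM argument: subproblem
  errors that decay with the residual do not affect the fixed point.
* **ALM warm restart across linearizations.**  After the first outer
  iteration, $L$, $S$, $Y$ are kept and $\mu$ backs off eight schedule
  steps instead of restarting from $\mu_0$; the constraint has moved only
  by the (small) re-warp.

Warped columns are rescaled to unit $\ell_2$ norm during solving — this
removes the trivial global-brightness direction from the alignment — and
the Jacobians receive the matching correction
$(I - aa^T)J/\lVert a\rVert$.  Results store the norms; user-facing
images are de-normalized.

**Residual semantics.**  With alignment enabled, the constraint the final
inner loop enforces is the *linearized* one,
$h = A\circ\tau + \sum_i J_i\Delta\tau_i\epsilon_i^T - L - S$, in the
normalized space.  `result.residual` and `converged` refer to that
quantity; $\lVert A\circ(\tau{+}\Delta\tau) - L - S\rVert$ differs by the
second-order linearization remainder, which no iterate controls.  At the
final outer iteration $\Delta\tau$ is at the `tol_outer` scale, so the
gap is negligible in practice but is not asserted.

## Warping and Jacobians

Affine parameters $(a_{11},a_{12},t_x,a_{21},a_{22},t_y)$ act in
pixel-center coordinates with the origin at the image center (rotations
about the center), output-to-input mapping, bilinear interpolation,
border replication (border frames would otherwise pollute $S$).  The
analytic Jacobian uses the **exact derivative of the bilinear
interpolant** — in-cell finite differences, bilinear in the transverse
coordinate, with central averaging exactly on grid lines — rather than
smoothed image gradients: the Jacobian is then the true derivative of
the implemented warp, finite-difference checks agree to interpolation
precision, and the linearization remainder is cleanly second order.
Samples clamped at the border have zero derivative in the clamped
coordinate, so warps of images with flat borders (all phantoms) are
differentiable where it matters.

## Two-pass pipeline

Pass 1 solves with the uniform penalty.  Per image, the sparse component
(de-normalized, so thresholds live on the $[0,1]$ intensity scale) is
binarized — Otsu's threshold on the nonzero magnitudes, AND an absolute
floor of 0.05 so sub-noise speckle never survives — and multiplied by a
saliency map of the *warped* observation (computed in the aligned frame
so that $P$ lives in the constraint's coordinates).  Pass 2 re-solves
with weights $\lambda(1-P)$, warm-started at the pass-1 transforms.
Final masks (nearest-neighbour) and recovered images (bilinear) are
resampled back through $\tau_i^{-1}$ into each image's original frame.

The saliency map follows the superpixel contrast-filter recipe: SLIC
abstraction (target 200 elements, compactness 0.1 — suited to smooth
MR-like images; blockier inputs need a larger compactness),
per-element **uniqueness** (intensity contrast with Gaussian position
weighting, $\sigma_p = 0.25\,\mathrm{diag}$) and **spatial distribution**
(positional variance with Gaussian intensity weighting,
$\sigma_c = 20/255$), combined as
$s = \mathrm{norm}(U)\exp(-k\,\mathrm{norm}(D))$ with $k = 6$, assigned
to pixels by bilateral position+intensity weighting, and min-max rescaled
to $[0,1]$ per image (the scale entering $P$ is therefore relative per
image).  Grayscale intensity replaces color distance — MR slices are
single-channel — and the element-pair sums are evaluated exactly in
$O(N^2)$; at $N \approx 200$ no approximate high-dimensional filtering is
warranted.

## Synthetic phantoms

The generator emulates the study conditions the decomposition assumes:

* **Anatomy**: `background_rank` (default 3) smooth templates — an
  elliptical brain with a soft boundary, Gaussian-bump texture, a darker
  central ventricle, band-limited by a σ = 1.2 px Gaussian so bilinear
  resampling is faithful — mixed per image with random convex (Dirichlet)
  weights.  The clean stack's rank is therefore *exactly* bounded by
  `background_rank`.
* **Lesions**: `round(tumor_fraction · n)` images (default 40% of 20)
  receive one blob: a disk whose boundary radius is modulated by random
  angular harmonics, smoothed with σ = radius/2 and re-thresholded —
  irregular but star-shaped, hence a single 4-connected component.
  Radius 5–9 px on a 64×64 grid; intensity raised by 0.35 with soft
  edges (hyperintense, FLAIR-like).  Masks are stored in the observed
  frame (warped with the image, largest component kept) because that is
  the frame segmentations are evaluated in.
* **Nuisance**: per-image rotation ±2° and translation ±2 px applied
  *after* lesion insertion (the lesion moves with the anatomy), then
  i.i.d. Gaussian noise σ = 0.01, then clipping to $[0,1]$.

What passing on phantoms does **not** show: robustness to bias fields,
multi-modal contrast, partial-volume effects, non-rigid anatomical
variability between subjects, or lesions that are not simply connected.
The phantom's anatomy is exactly low rank; real inter-subject stacks are
only approximately so, and real-data performance is correspondingly
lower.

## Evaluation metrics

SSIM with the standard constants $c_1=(0.01R)^2$, $c_2=(0.03R)^2$,
$R = 1$: `global` mode (default) evaluates the single formula with
whole-image moments; `windowed` mode averages over 11×11 Gaussian
windows (σ = 1.5, population moments) and matches
`skimage.metrics.structural_similarity` to 1e-6 in the corresponding
configuration.  Dice is $2|G\cap T|/(|G|+|T|)$ with the degenerate cases
fixed as empty-vs-empty = 1 and empty-vs-nonempty = 0.

## Numerical choices and degenerate inputs

* Singleton groups turn $\Omega$ into the weighted $\ell_1$ norm and the
  prox into soft thresholding exactly (one dual iteration); with
  alignment off the solver then reproduces classical RPCA step for step.
* Zero weights make the prox the identity on the affected groups (an
  unpenalized region is absorbed by $S$); weight ties inside a window
  need no explicit tie-break — the dual projection distributes the load.
* Constant images: zero Jacobian (no alignment signal), all-zero
  saliency (nothing salient), empty masks from the binarizer.
* All-zero observation matrices decompose trivially and are handled
  before any SVD.
* Non-convergence is a *flag* (`converged=False`, history attached) for
  the ALM loops, but an *error* for the prox dual (naming the worst
  column and its gap): an inaccurate prox silently corrupts the
  decomposition, whereas an unconverged ALM is a legitimate, inspectable
  outcome.

## Problem sizes

Default test and reproduction runs use 20 images of 64×64 (the full
pipeline, about three minutes on one CPU) and 8 images of 32×32 for unit
tests; these sizes exercise every code path at comfortable margins of
the decomposition's recovery regime.  The planted robust-PCA recovery
test uses an 80×40 rank-2 matrix with 5% spikes: at 40×20 the convex
optimum no longer coincides with the planted pair for some draws, i.e.
the instance leaves the exact-recovery regime, while 80×40 recovers to
1e-8 across seeds.

## Known limitations

* 2-D slices only; no 3-D volumetric decomposition.
* Affine alignment only — capture range of a few pixels/degrees; no
  non-rigid registration.
* The adaptive pass inherits pass-1 mistakes: a lesion entirely missed
  by pass 1 gets no weight relief in pass 2 (the probability map is a
  refinement, not a detector of its own).
* Recovered intensities near the lesion boundary can retain slight
  artifacts, the known cost of switching penalty strength across the
  boundary.
* The outer loop often reaches `outer_max` with $\lVert\Delta\tau\rVert_F$
  at the 1e-3 scale rather than `tol_outer`: a global affine gauge
  freedom (all images re-warped by one common map) leaves a flat
  direction along which $\Delta\tau$ drifts harmlessly.  The
  `outer_converged` flag reports this honestly; the decomposition itself
  is unaffected.
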