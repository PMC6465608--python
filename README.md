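# tls2d — transformed low-rank + structured-sparse decomposition of brain MR stacks

`tls2d` simultaneously **aligns** a stack of 2-D brain MR slices,
**recovers** a quasi-normal (lesion-free) version of each image, and
**segments** the lesions — with no labeled training data.  It is aimed at
researchers in medical image computing who need pathological regions
removed or delineated before downstream steps such as atlas construction,
registration, or atlas-based segmentation.

## The model

Vectorize each of the $n$ images into the columns of
$A \in \mathbb{R}^{m \times n}$ ($m = w \cdot h$).  Healthy anatomy is
nearly identical across subjects, so the aligned tumor-free stack is low
rank; a lesion is a contiguous, image-specific outlier.  The package
solves

$$\min_{L,S,\tau}\; \lVert L\rVert_* + \lambda\,\Omega(S)
\quad \text{s.t.}\quad A \circ \tau = L + S,$$

where $\tau = (\tau_1,\dots,\tau_n)$ are per-image affine transforms,
$\lVert L \rVert_*$ is the nuclear norm (convex surrogate of rank), and

$$\Omega(S) = \sum_{i=1}^{n}\sum_{g \in G} \lVert \mathrm{mat}(S_i)_g \rVert_\infty$$

is a structured sparsity norm over the set $G$ of all overlapping
3×3 pixel windows — activating one pixel pays for its whole window, so
the sparse support organizes into contiguous patches instead of salt-and-
pepper speckle.  The nonconvex warp is handled by iterative linearization
$A\circ(\tau + \Delta\tau) \approx A\circ\tau + \sum_i J_i \Delta\tau_i
\epsilon_i^T$; each linearized problem is solved with an inexact
augmented-Lagrangian scheme alternating singular-value thresholding for
$L$, the proximal operator of $\Omega$ for $S$ (solved through its dual
by accelerated projected gradient), and a closed-form least-squares step
for $\Delta\tau$.

A second pass sharpens the recovery: the first pass's binarized sparse
component is multiplied by a superpixel contrast saliency map to form a
tumor probability map $P$, and the problem is re-solved with the adaptive
weight $\lambda(1-P)$ — the sparsity penalty is relaxed exactly where the
evidence says "tumor", so $S$ absorbs the lesion fully and $L$ restores
plausible normal anatomy there, while healthy regions stay strongly
penalized and sharp.

Because public tumor MR datasets are external downloads, the package
ships a first-class phantom generator (`tls2d.phantom`) that plants the
exact structure the model assumes — an exactly rank-limited smooth
anatomy stack, irregular hyperintense blobs, affine jitter, noise — and
keeps the ground truth for quantitative evaluation.

## Worked example

```python
import numpy as np
from tls2d import TLS2D, PhantomConfig, generate_phantom

truth = generate_phantom(PhantomConfig(
    n_images=8, width=32, height=32, background_rank=2,
    tumor_fraction=0.25, tumor_radius_range=(4.0, 6.0),
    max_translation=1.0, max_rotation=1.0, seed=11))

model = TLS2D(truth.observed_images)
res = model.fit_two_pass()
print(res.summary())
report = res.evaluate(truth)
print(f"mean Dice vs planted masks: {report['mean_dice']:.3f}")
print(f"mean SSIM vs planted clean: {report['mean_ssim']:.3f}")
```

prints

```
Transformed low-rank + structured-sparse decomposition
========================================================
images (n)                       8
pixels per image (m)             1024
lambda                           0.03125
group structure                  3x3
outer iterations                 10
total inner iterations           113
converged (inner)                True
outer converged (|dtau|)         False
relative residual                9.574e-08
rank(L)                          8
nuclear norm ||L||_*             2.9643
Omega(S)                         0.1121
--------------------------------------------------------
two-pass pipeline                uniform -> P map -> adaptive
images with lesions found        2
mean lesion area (px)            73.5

mean Dice vs planted masks: 0.984
mean SSIM vs planted clean: 0.999
```

Reading the output: the solver met its constraint tolerance (relative
residual ≈ 1e-7), found the two planted lesions and no false ones, the
segmentations overlap the planted masks almost perfectly (Dice 0.984),
and the recovered images are nearly indistinguishable from the planted
tumor-free anatomy (SSIM 0.999).  `lambda` is the auto-chosen sparsity
weight $1/\sqrt{\max(m,n)}$.

`res.recovered_images()`, `res.tumor_masks()`, `res.transforms` expose
the estimates; `res.plot_decomposition(i)` shows the aligned observation,
low-rank, sparse and mask panels for image `i`.  A plain
robust-PCA baseline is available as `tls2d.RPCA(images).fit()`.

## Command line

```bash
tls2d simulate --config cfg.yaml --out phantom/      # synthetic stack + truth
tls2d run --in phantom/ --out results/ --truth phantom/   # full pipeline
tls2d rpca --in phantom/ --out rpca/                 # baseline decomposition
tls2d saliency --in img.png --out sal.png            # saliency map only
tls2d evaluate --pred results/ --truth phantom/ --report metrics.json
```

Every run writes its fully resolved configuration and a manifest next to
its outputs, so results are reproducible from the output directory alone.

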