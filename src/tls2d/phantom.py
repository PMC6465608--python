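"""Synthetic brain-like phantom stacks with planted ground truth.

The decomposition model assumes a stack of near-identical "normal"
anatomy images (so the clean stack is low rank across images), a minority
of images carrying a contiguous hyperintense lesion (structured-sparse
outliers, FLAIR-like appearance), and small affine misalignments between
images.  The generator plants exactly that structure and retains the
truth needed for parameter-recovery tests:

* ``background_rank`` smooth anatomy templates -- a shared elliptical
  "brain" with Gaussian-bump cortex texture and a darker central
  "ventricle" -- mixed with random convex weights per image, so the
  vectorized clean stack has rank at most ``background_rank`` exactly.
* tumors as thresholded smoothed blobs with irregular (radially
  modulated) boundaries, each a single 4-connected component, inserted
  additively before misalignment so the lesion moves with the anatomy.
* per-image affine jitter (rotation about the image center plus
  translation), then i.i.d. Gaussian noise, then clipping to [0, 1].

Tumor masks are stored in the observed-image frame (warped together with
the image) because that is the frame segmentations are evaluated in;
clean images are stored in the aligned frame, and the true transforms map
between the two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .alignment import affine_warp, warp_mask

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "write_phantom",
    "load_phantom",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic stack.

    Defaults describe a modest desk-scale stack: 20 images of 64x64
    pixels, a rank-3 anatomy background, 40% of images carrying one
    lesion of 5--9 px radius raised by 0.35 intensity units, +-2 px /
    +-2 degree jitter and noise sigma 0.01 on the [0, 1] scale.
    """

    n_images: int = 20
    width: int = 64
    height: int = 64
    background_rank: int = 3
    tumor_fraction: float = 0.4
    tumor_radius_range: tuple[float, float] = (5.0, 9.0)
    tumor_intensity_delta: float = 0.35
    max_translation: float = 2.0
    max_rotation: float = 2.0
    noise_sigma: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("width and height must be at least 16")
        if self.n_images < 3:
            raise ValueError("need at least 3 images")
        if not 0 < self.background_rank < self.n_images:
            raise ValueError(
                "background_rank must be positive and below n_images"
            )
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        rmin, rmax = self.tumor_radius_range
        if not 0 < rmin <= rmax:
            raise ValueError("invalid tumor_radius_range")
        if rmax > min(self.width, self.height) / 3:
            raise ValueError(
                "tumor radius too large: max radius must not exceed "
                "min(width, height)/3, or the lesion would not be sparse"
            )
        if self.tumor_intensity_delta <= 0:
            raise ValueError("tumor_intensity_delta must be positive "
                             "(lesions are hyperintense)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class PhantomTruth:
    """Planted ground truth alongside the observed stack.

    ``clean_images``: tumor-free, aligned anatomy (n, h, w).
    ``tumor_masks``: boolean lesion masks in the observed frame (n, h, w);
    all-zero for images without a lesion.
    ``true_transforms``: per-image affine parameters (n, 6) applied when
    producing the observations.
    ``observed_images``: the misaligned, lesioned, noisy stack (n, h, w).
    """

    clean_images: np.ndarray
    tumor_masks: np.ndarray
    true_transforms: np.ndarray
    observed_images: np.ndarray
    config: PhantomConfig

    @property
    def n_images(self) -> int:
        return self.observed_images.shape[0]

    def tumor_indices(self) -> np.ndarray:
        """Indices of images whose mask is nonempty."""
        return np.flatnonzero(self.tumor_masks.any(axis=(1, 2)))

    def warped_clean(self, i: int) -> np.ndarray:
        """The tumor-free counterpart of observed image ``i`` (its frame)."""
        return affine_warp(self.clean_images[i], self.true_transforms[i])


def _ellipse(h, w, cy, cx, ry, rx, theta=0.0):
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    y = yy - cy
    x = xx - cx
    c, s = np.cos(theta), np.sin(theta)
    xr = c * x + s * y
    yr = -s * x + c * y
    return (xr / rx) ** 2 + (yr / ry) ** 2


def _anatomy_template(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """One smooth brain-like template in [0, 1]."""
    cy, cx = (h - 1) / 2, (w - 1) / 2
    d2 = _ellipse(h, w, cy, cx, 0.44 * h, 0.40 * w)
    brain = 1.0 / (1.0 + np.exp((d2 - 1.0) * 12.0))  # soft brain boundary
    tex = np.zeros((h, w))
    for _ in range(rng.integers(5, 9)):
        by = rng.uniform(0.2 * h, 0.8 * h)
        bx = rng.uniform(0.2 * w, 0.8 * w)
        sig = rng.uniform(0.06, 0.16) * min(h, w)
        amp = rng.uniform(-0.25, 0.35)
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        tex += amp * np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sig**2))
    vent = _ellipse(
        h, w, cy + rng.uniform(-2, 2), cx + rng.uniform(-2, 2),
        0.13 * h, 0.09 * w, rng.uniform(-0.4, 0.4),
    )
    vent_mask = 1.0 / (1.0 + np.exp((vent - 1.0) * 10.0))
    img = brain * (0.55 + tex) - 0.30 * vent_mask
    # band-limit: MR-like smoothness, keeps bilinear resampling faithful
    img = ndimage.gaussian_filter(img, sigma=1.2)
    return np.clip(img, 0.0, 1.0)


def _tumor_blob(
    h: int, w: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """A single irregular, 4-connected lesion mask of roughly the radius.

    A disk whose boundary radius is modulated by a few random angular
    harmonics (star-shaped, hence connected), smoothed with sigma =
    radius/2 and re-thresholded for a soft, irregular outline.
    """
    cy, cx = (h - 1) / 2, (w - 1) / 2
    # sample a center inside a central "brain" ellipse
    for _ in range(1000):
        y = rng.uniform(0.2 * h, 0.8 * h)
        x = rng.uniform(0.2 * w, 0.8 * w)
        if _ellipse(h, w, cy, cx, 0.30 * h, 0.27 * w)[int(y), int(x)] <= 1.0:
            break
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d = np.hypot(yy - y, xx - x)
    phi = np.arctan2(yy - y, xx - x)
    rb = np.full_like(d, radius)
    for harm in (2, 3, 5):
        rb = rb + radius * rng.uniform(0.0, 0.12) * np.cos(
            harm * phi + rng.uniform(0, 2 * np.pi)
        )
    base = (d <= rb).astype(float)
    smooth = ndimage.gaussian_filter(base, sigma=radius / 2.0)
    mask = smooth > 0.5
    # keep the component containing the center (guards against stray pixels)
    labels, nlab = ndimage.label(mask, structure=_FOUR_CONN)
    if nlab == 0:
        mask = d <= max(radius, 1.5)
        labels, nlab = ndimage.label(mask, structure=_FOUR_CONN)
    center_label = labels[int(round(y)), int(round(x))]
    if center_label == 0:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, nlab + 1))
        center_label = 1 + int(np.argmax(sizes))
    mask = labels == center_label
    return ndimage.binary_fill_holes(mask, structure=_FOUR_CONN)


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Generate a phantom stack; bit-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w, n = config.height, config.width, config.n_images
    r = config.background_rank

    templates = np.stack([_anatomy_template(h, w, rng) for _ in range(r)])
    weights = rng.dirichlet(np.full(r, 2.0), size=n)  # convex: keeps [0,1]
    clean = np.einsum("nk,khw->nhw", weights, templates)

    n_tumor = int(round(config.tumor_fraction * n))
    tumor_idx = np.sort(rng.choice(n, size=n_tumor, replace=False))

    rmin, rmax = config.tumor_radius_range
    masks_aligned = np.zeros((n, h, w), dtype=bool)
    lesioned = clean.copy()
    for i in tumor_idx:
        radius = rng.uniform(rmin, rmax)
        blob = _tumor_blob(h, w, radius, rng)
        masks_aligned[i] = blob
        # soft-edged additive hyperintensity
        profile = ndimage.gaussian_filter(blob.astype(float), sigma=1.0)
        if profile.max() > 0:
            profile = profile / profile.max()
        lesioned[i] = np.clip(
            lesioned[i] + config.tumor_intensity_delta * profile, 0.0, 1.0
        )

    transforms = np.zeros((n, 6))
    observed = np.empty((n, h, w))
    masks = np.zeros((n, h, w), dtype=bool)
    for i in range(n):
        theta = np.deg2rad(
            rng.uniform(-config.max_rotation, config.max_rotation)
        )
        tx = rng.uniform(-config.max_translation, config.max_translation)
        ty = rng.uniform(-config.max_translation, config.max_translation)
        tau = np.array(
            [np.cos(theta), -np.sin(theta), tx,
             np.sin(theta), np.cos(theta), ty]
        )
        transforms[i] = tau
        img = affine_warp(lesioned[i], tau)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        observed[i] = np.clip(img, 0.0, 1.0)
        if masks_aligned[i].any():
            warped = warp_mask(masks_aligned[i], tau)
            labels, nlab = ndimage.label(warped, structure=_FOUR_CONN)
            if nlab > 1:  # nearest-neighbour resampling can shed pixels
                sizes = ndimage.sum_labels(
                    warped, labels, index=np.arange(1, nlab + 1)
                )
                warped = labels == (1 + int(np.argmax(sizes)))
            masks[i] = warped

    return PhantomTruth(
        clean_images=clean,
        tumor_masks=masks,
        true_transforms=transforms,
        observed_images=observed,
        config=config,
    )


# ---------------------------------------------------------------------------
# plain-text / PNG persistence

_EXPECTED = ("config.txt", "transforms.txt")


def _write_png16(path: Path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.clip(image, 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 65535).astype(np.uint16))


def _read_png16(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    return arr.astype(float) / 65535.0


def write_phantom(truth: PhantomTruth, directory: str | Path) -> None:
    """Persist a phantom: 16-bit PNG images, 8-bit PNG masks, text metadata."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = truth.n_images
    for i in range(n):
        _write_png16(directory / f"clean_{i:03d}.png", truth.clean_images[i])
        _write_png16(
            directory / f"observed_{i:03d}.png", truth.observed_images[i]
        )
        iio.imwrite(
            directory / f"mask_{i:03d}.png",
            (truth.tumor_masks[i].astype(np.uint8) * 255),
        )
    with open(directory / "transforms.txt", "w") as fh:
        for i in range(n):
            vals = " ".join(f"{v:.17g}" for v in truth.true_transforms[i])
            fh.write(f"tau_{i}: {vals}\n")
    with open(directory / "config.txt", "w") as fh:
        for key, value in asdict(truth.config).items():
            if isinstance(value, tuple):
                value = " ".join(str(v) for v in value)
            fh.write(f"{key}: {value}\n")


def _parse_config(path: Path) -> PhantomConfig:
    fields: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    rr = fields["tumor_radius_range"].split()
    return PhantomConfig(
        n_images=int(fields["n_images"]),
        width=int(fields["width"]),
        height=int(fields["height"]),
        background_rank=int(fields["background_rank"]),
        tumor_fraction=float(fields["tumor_fraction"]),
        tumor_radius_range=(float(rr[0]), float(rr[1])),
        tumor_intensity_delta=float(fields["tumor_intensity_delta"]),
        max_translation=float(fields["max_translation"]),
        max_rotation=float(fields["max_rotation"]),
        noise_sigma=float(fields["noise_sigma"]),
        seed=int(fields["seed"]),
    )


def load_phantom(directory: str | Path) -> PhantomTruth:
    """Load a phantom written by :func:`write_phantom`.

    Raises ``FileNotFoundError`` naming the missing file(s), and
    ``ValueError`` on shape-inconsistent images.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    missing = [f for f in _EXPECTED if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"phantom directory {directory} is missing: "
            + ", ".join(missing)
            + " (expected config.txt, transforms.txt, clean_*.png, "
            "observed_*.png, mask_*.png)"
        )
    config = _parse_config(directory / "config.txt")
    n = config.n_images
    shape = (config.height, config.width)

    taus = {}
    for line in (directory / "transforms.txt").read_text().splitlines():
        m = re.match(r"tau_(\d+):\s*(.*)", line.strip())
        if m:
            taus[int(m.group(1))] = np.array(
                [float(v) for v in m.group(2).split()]
            )
    transforms = np.zeros((n, 6))
    for i in range(n):
        if i not in taus:
            raise ValueError(f"transforms.txt is missing tau_{i}")
        transforms[i] = taus[i]

    def read_stack(prefix, reader):
        out = []
        for i in range(n):
            path = directory / f"{prefix}_{i:03d}.png"
            if not path.exists():
                raise FileNotFoundError(f"missing file {path}")
            arr = reader(path)
            if arr.shape != shape:
                raise ValueError(
                    f"{path} has shape {arr.shape}, expected {shape}"
                )
            out.append(arr)
        return np.stack(out)

    clean = read_stack("clean", _read_png16)
    observed = read_stack("observed", _read_png16)
    masks = read_stack("mask", lambda p: iio.imread(p) > 127)
    return PhantomTruth(
        clean_images=clean,
        tumor_masks=masks,
        true_transforms=transforms,
        observed_images=observed,
        config=config,
    )
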