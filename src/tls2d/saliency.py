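"""Contrast-based saliency and the tumor probability map.

An image is abstracted into perceptually homogeneous elements
(SLIC superpixels); each element gets two contrast measures:

* uniqueness ``U_i = sum_j (c_i - c_j)^2 w_p(p_i, p_j)`` -- how much the
  element's mean intensity ``c_i`` stands out from other elements, with a
  per-``i`` normalized Gaussian weight in element-centroid distance, so
  nearby elements count more;
* spatial distribution ``D_i = sum_j ||p_j - mu_i||^2 w_c(c_i, c_j)`` --
  the positional variance of the element's intensity across the image
  (``mu_i`` the ``w_c``-weighted mean position, ``w_c`` a per-``i``
  normalized Gaussian in intensity similarity).  Compact intensities
  (low ``D``) are salient; widely scattered ones are background.

Element saliency ``s_i = norm(U_i) * exp(-k * norm(D_i))`` is pushed back
to pixels by bilateral (position + intensity) Gaussian weighting and the
map rescaled to [0, 1].  Element pair sums are evaluated exactly
(O(N^2), N a few hundred).

The tumor probability map is the elementwise product of a binarized
sparse component and this saliency map: a pixel is probably tumor when
the decomposition flags it *and* it is visually conspicuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SaliencyParams",
    "SaliencyElements",
    "abstract_elements",
    "uniqueness",
    "distribution",
    "assign_saliency",
    "compute_saliency",
    "tumor_probability",
]


@dataclass(frozen=True)
class SaliencyParams:
    """Tunable constants; defaults follow the contrast-filter convention.

    ``sigma_p`` is the uniqueness position scale as a fraction of the
    image diagonal; ``sigma_c`` the intensity scale on [0, 1]; ``k`` the
    exponent weighting spatial compactness; the ``upsample_*`` scales
    control the bilateral element-to-pixel assignment.
    """

    n_elements: int = 200
    compactness: float = 0.1
    sigma_p: float = 0.25
    sigma_c: float = 20.0 / 255.0
    k: float = 6.0
    upsample_sigma_p: float = 0.1
    upsample_sigma_c: float = 20.0 / 255.0


@dataclass
class SaliencyElements:
    """Superpixel abstraction plus per-element statistics."""

    labels: np.ndarray  # (h, w) int, 0-based, contiguous
    intensity: np.ndarray  # (N,) mean intensity per element
    position: np.ndarray  # (N, 2) mean (row, col) per element
    shape: tuple[int, int]
    uniqueness: np.ndarray | None = None
    distribution: np.ndarray | None = None
    saliency: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return len(self.intensity)


def abstract_elements(
    image: np.ndarray,
    n_elements: int = 200,
    compactness: float = 0.1,
) -> SaliencyElements:
    """SLIC superpixel abstraction of a grayscale image.

    Returns roughly ``n_elements`` perceptually homogeneous regions with
    their mean intensity and centroid.  A constant image may collapse to
    a single element; downstream functions handle that degenerate case.
    """
    if n_elements < 2:
        raise ValueError("n_elements must be at least 2")
    from skimage.segmentation import slic

    image = np.asarray(image, dtype=float)
    if np.ptp(image) < 1e-12:
        labels = np.zeros(image.shape, dtype=int)
    else:
        labels = slic(
            image,
            n_segments=n_elements,
            compactness=compactness,
            channel_axis=None,
            start_label=0,
            enforce_connectivity=True,
        )
        # relabel to a contiguous 0..N-1 range
        _, labels = np.unique(labels, return_inverse=True)
        labels = labels.reshape(image.shape)
    n = labels.max() + 1
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n).astype(float)
    intensity = np.bincount(flat, weights=image.ravel(), minlength=n) / counts
    yy, xx = np.meshgrid(
        np.arange(image.shape[0]), np.arange(image.shape[1]), indexing="ij"
    )
    pos = np.column_stack(
        [
            np.bincount(flat, weights=yy.ravel(), minlength=n) / counts,
            np.bincount(flat, weights=xx.ravel(), minlength=n) / counts,
        ]
    )
    return SaliencyElements(
        labels=labels, intensity=intensity, position=pos, shape=image.shape
    )


def uniqueness(
    elements: SaliencyElements, sigma_p: float | None = None
) -> np.ndarray:
    """Per-element intensity uniqueness (module docstring).

    ``sigma_p`` in pixels; defaults to a quarter of the image diagonal.
    """
    if sigma_p is None:
        sigma_p = 0.25 * float(np.hypot(*elements.shape))
    c = elements.intensity
    p = elements.position
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * sigma_p**2))
    w /= w.sum(axis=1, keepdims=True)
    U = (w * (c[:, None] - c[None, :]) ** 2).sum(axis=1)
    elements.uniqueness = U
    return U


def distribution(
    elements: SaliencyElements, sigma_c: float = 20.0 / 255.0
) -> np.ndarray:
    """Per-element spatial spread of similar intensities (module docstring).

    Low values mean the element's intensity is spatially compact, which
    marks foreground; large spread marks background.
    """
    c = elements.intensity
    p = elements.position
    w = np.exp(-((c[:, None] - c[None, :]) ** 2) / (2.0 * sigma_c**2))
    w /= w.sum(axis=1, keepdims=True)
    mu = w @ p  # (N, 2) weighted mean position per element
    d2 = ((p[None, :, :] - mu[:, None, :]) ** 2).sum(-1)
    D = (w * d2).sum(axis=1)
    elements.distribution = D
    return D


def _rescale01(x: np.ndarray) -> np.ndarray:
    rng = np.ptp(x)
    if rng < 1e-15:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def assign_saliency(
    elements: SaliencyElements,
    k: float = 6.0,
    upsample_sigma_p: float | None = None,
    upsample_sigma_c: float = 20.0 / 255.0,
) -> np.ndarray:
    """Combine the two contrast measures into a per-pixel map in [0, 1].

    Element saliency ``s = norm(U) * exp(-k * norm(D))`` (min-max
    normalization; zero range gives zeros) is assigned to pixels by
    bilateral Gaussian weighting in position and intensity, then the map
    is rescaled to [0, 1].  A constant image yields an all-zero map.
    """
    if elements.uniqueness is None or elements.distribution is None:
        raise ValueError("compute uniqueness and distribution first")
    h, w = elements.shape
    if upsample_sigma_p is None:
        upsample_sigma_p = 0.1 * float(np.hypot(h, w))
    s = _rescale01(elements.uniqueness) * np.exp(
        -k * _rescale01(elements.distribution)
    )
    elements.saliency = s
    if np.ptp(s) < 1e-15 and s.max() == 0.0:
        return np.zeros(elements.shape)

    # bilateral element-to-pixel assignment
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix_pos = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    pix_int = elements.intensity[elements.labels].ravel()
    d2 = ((pix_pos[:, None, :] - elements.position[None, :, :]) ** 2).sum(-1)
    di2 = (pix_int[:, None] - elements.intensity[None, :]) ** 2
    logw = -d2 / (2 * upsample_sigma_p**2) - di2 / (2 * upsample_sigma_c**2)
    logw -= logw.max(axis=1, keepdims=True)
    wgt = np.exp(logw)
    wgt /= wgt.sum(axis=1, keepdims=True)
    sal = (wgt @ s).reshape(h, w)
    return _rescale01(sal)


def compute_saliency(
    image: np.ndarray, params: SaliencyParams | None = None
) -> np.ndarray:
    """Full saliency pipeline for one grayscale image; map in [0, 1]."""
    if params is None:
        params = SaliencyParams()
    elements = abstract_elements(
        image, n_elements=params.n_elements, compactness=params.compactness
    )
    diag = float(np.hypot(*elements.shape))
    uniqueness(elements, sigma_p=params.sigma_p * diag)
    distribution(elements, sigma_c=params.sigma_c)
    return assign_saliency(
        elements,
        k=params.k,
        upsample_sigma_p=params.upsample_sigma_p * diag,
        upsample_sigma_c=params.upsample_sigma_c,
    )


def tumor_probability(
    binary_sparse: np.ndarray, saliency_map: np.ndarray
) -> np.ndarray:
    """Elementwise product of a lesion mask and a saliency map.

    The result is zero outside the mask and bounded by the saliency
    inside it; it drives the adaptive sparsity weight ``lam * (1 - P)``.
    """
    binary_sparse = np.asarray(binary_sparse)
    saliency_map = np.asarray(saliency_map, dtype=float)
    if binary_sparse.shape != saliency_map.shape:
        raise ValueError(
            f"mask shape {binary_sparse.shape} != saliency shape "
            f"{saliency_map.shape}"
        )
    if saliency_map.min() < 0 or saliency_map.max() > 1:
        raise ValueError("saliency map must lie in [0, 1]")
    return binary_sparse.astype(float) * saliency_map
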