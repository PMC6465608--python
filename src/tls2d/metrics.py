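"""Evaluation metrics: structural similarity (SSIM) and Dice overlap."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["SSIMParams", "ssim", "dice"]


@dataclass(frozen=True)
class SSIMParams:
    """SSIM constants and mode.

    ``c1 = (0.01 R)^2`` and ``c2 = (0.03 R)^2`` by convention, with ``R``
    the dynamic range.  ``mode="global"`` evaluates the single-formula
    SSIM with whole-image moments; ``mode="windowed"`` averages the local
    SSIM over Gaussian windows (win_size 11, sigma 1.5, population
    moments), the common image-quality variant.
    """

    data_range: float = 1.0
    c1: float | None = None
    c2: float | None = None
    mode: str = "global"
    win_size: int = 11
    sigma: float = 1.5

    def constants(self) -> tuple[float, float]:
        c1 = (0.01 * self.data_range) ** 2 if self.c1 is None else self.c1
        c2 = (0.03 * self.data_range) ** 2 if self.c2 is None else self.c2
        if c1 <= 0 or c2 <= 0:
            raise ValueError("stabilization constants must be positive")
        return c1, c2


def ssim(
    x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None
) -> float:
    """Structural similarity of two images.

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
                 ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))
    """
    if params is None:
        params = SSIMParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    c1, c2 = params.constants()
    if params.mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        return float(
            (2 * mx * my + c1)
            * (2 * cxy + c2)
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    if params.mode != "windowed":
        raise ValueError(f"unknown SSIM mode {params.mode!r}")

    # Gaussian-window local moments (population normalization), mean of
    # the local SSIM map over the valid interior.
    truncate = ((params.win_size - 1) / 2 - 0.5) / params.sigma

    def filt(a):
        return ndimage.gaussian_filter(
            a, sigma=params.sigma, truncate=truncate, mode="nearest"
        )

    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    s = (
        (2 * ux * uy + c1)
        * (2 * cxy + c2)
        / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    )
    pad = (params.win_size - 1) // 2
    interior = s[tuple(slice(pad, dim - pad) for dim in s.shape)]
    return float(interior.mean())


def dice(T: np.ndarray, G: np.ndarray) -> float:
    """Dice overlap ``2|G n T| / (|G| + |T|)`` of two binary masks.

    Two empty masks agree perfectly (1.0); empty vs nonempty gives 0.
    """
    T = np.asarray(T).astype(bool)
    G = np.asarray(G).astype(bool)
    if T.shape != G.shape:
        raise ValueError(f"shape mismatch: {T.shape} vs {G.shape}")
    denom = T.sum() + G.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(T, G).sum() / denom)
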