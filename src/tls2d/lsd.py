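"""Classical low-rank + sparse decomposition (robust PCA) via inexact ALM.

The observation matrix ``A`` stacks ``n`` vectorized ``w x h`` images as
columns.  Robust PCA splits ``A = L + S`` with ``L`` low rank (the shared,
"normal" appearance across the stack) and ``S`` elementwise sparse (the
column-specific outliers, e.g. lesions), by solving the convex program

    min  ||L||_* + lam * ||S||_1   s.t.  A = L + S

with the inexact augmented-Lagrangian scheme of Lin et al.  The two
shrinkage operators used by every solver in this package --
:func:`soft_threshold` (prox of the l1 norm) and
:func:`singular_value_threshold` (prox of the nuclear norm) -- live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "ImageStack",
    "DecompositionResult",
    "soft_threshold",
    "singular_value_threshold",
    "rpca_alm",
    "default_lambda",
]


@dataclass
class ImageStack:
    """A stack of equally sized grayscale images as a column matrix.

    Parameters
    ----------
    data
        ``(m, n)`` array; column ``i`` is image ``i`` flattened row-major,
        with ``m = width * height``.
    width, height
        Image geometry in pixels.
    names
        Optional per-column identifiers (e.g. source filenames); kept in
        column order.
    """

    data: np.ndarray
    width: int
    height: int
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("stack data must be a 2-D (m, n) matrix")
        if self.data.shape[0] != self.width * self.height:
            raise ValueError(
                f"m = {self.data.shape[0]} does not match "
                f"width*height = {self.width * self.height}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite entries")

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_images(
        cls, images: Sequence[np.ndarray], names: list[str] | None = None
    ) -> "ImageStack":
        """Build a stack from a sequence of equal-size 2-D arrays."""
        images = [np.asarray(im, dtype=float) for im in images]
        if not images:
            raise ValueError("empty image sequence")
        h, w = images[0].shape
        for k, im in enumerate(images):
            if im.shape != (h, w):
                raise ValueError(
                    f"image {k} has shape {im.shape}, expected {(h, w)}"
                )
        data = np.column_stack([im.ravel() for im in images])
        return cls(data=data, width=w, height=h, names=names)

    def column_image(self, i: int) -> np.ndarray:
        """Return column ``i`` reshaped to ``(height, width)``."""
        return self.data[:, i].reshape(self.height, self.width)

    def to_images(self) -> list[np.ndarray]:
        return [self.column_image(i) for i in range(self.n)]


@dataclass
class DecompositionResult:
    """Output of a low-rank + sparse solver.

    ``L``, ``S`` and ``Y`` live in the space the solver actually operated
    in (column-normalized if normalization was enabled); ``column_norms``
    holds the scale needed to map back to intensity units, and
    ``constraint_matrix`` is the matrix the constraint ``= L + S`` was
    enforced against (the warped, possibly normalized observations).
    """

    L: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    mu: float
    converged: bool
    residual: float
    history: list[dict[str, float]] = field(default_factory=list)
    transforms: np.ndarray | None = None
    column_norms: np.ndarray | None = None
    constraint_matrix: np.ndarray | None = None
    width: int | None = None
    height: int | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.history)

    def denormalized(self, M: np.ndarray) -> np.ndarray:
        """Rescale a solver-space matrix back to intensity units."""
        if self.column_norms is None:
            return M
        return M * self.column_norms[np.newaxis, :]

    def low_rank_images(self) -> list[np.ndarray]:
        if self.width is None or self.height is None:
            raise ValueError("result carries no image geometry")
        Ld = self.denormalized(self.L)
        return [
            Ld[:, i].reshape(self.height, self.width)
            for i in range(Ld.shape[1])
        ]

    def sparse_images(self) -> list[np.ndarray]:
        if self.width is None or self.height is None:
            raise ValueError("result carries no image geometry")
        Sd = self.denormalized(self.S)
        return [
            Sd[:, i].reshape(self.height, self.width)
            for i in range(Sd.shape[1])
        ]

    def history_frame(self):
        """Convergence history as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(self.history)


def soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise soft thresholding ``sign(x) * max(|x| - tau, 0)``.

    The proximal operator of ``tau * ||.||_1``; shrinks every entry toward
    zero by ``tau`` and zeroes the dead zone ``|x| <= tau``.
    """
    if tau < 0:
        raise ValueError(f"threshold must be nonnegative, got {tau}")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def singular_value_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Soft-threshold the singular values of ``M`` by ``tau``.

    Closed-form proximal operator of ``tau * ||.||_*``: with
    ``M = U diag(s) V^T`` (thin SVD), returns ``U diag([s - tau]_+) V^T``.
    """
    if tau < 0:
        raise ValueError(f"threshold must be nonnegative, got {tau}")
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("input matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s[np.newaxis, :]) @ Vt


def default_lambda(m: int, n: int) -> float:
    """Standard RPCA weight ``1 / sqrt(max(m, n))``."""
    return 1.0 / np.sqrt(max(m, n))


def rpca_alm(
    A: ImageStack | np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
    rho: float = 1.25,
    mu0_factor: float = 1.25,
    mu_max_factor: float = 1e7,
) -> DecompositionResult:
    """Robust PCA by the inexact augmented-Lagrangian method.

    Alternates a singular-value-threshold step for ``L`` (threshold
    ``1/mu``), a soft-threshold step for ``S`` (threshold ``lam/mu``), the
    multiplier update ``Y <- Y + mu (A - L - S)`` and a geometric increase
    of the penalty ``mu``.  Stops when the relative primal residual
    ``||A - L - S||_F / ||A||_F`` drops below ``tol``.

    Parameters
    ----------
    A
        Observation matrix or :class:`ImageStack`.
    lam
        Sparsity weight; default ``1/sqrt(max(m, n))``.
    tol
        Relative primal-residual stopping tolerance.
    max_iter
        Iteration cap; hitting it flags the result unconverged rather than
        raising.
    """
    if isinstance(A, ImageStack):
        width, height = A.width, A.height
        A = A.data
    else:
        width = height = None
        A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty observation matrix")
    m, n = A.shape
    if lam is None:
        lam = default_lambda(m, n)
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")

    norm_A = np.linalg.norm(A)
    if norm_A == 0:
        # Degenerate but valid: the zero matrix decomposes trivially.
        Z = np.zeros_like(A)
        hist = [
            {
                "residual": 0.0,
                "nuclear_norm": 0.0,
                "sparsity_norm": 0.0,
                "rank": 0,
                "mu": 1.0,
            }
        ]
        return DecompositionResult(
            L=Z, S=Z.copy(), Y=Z.copy(), mu=1.0, converged=True,
            residual=0.0, history=hist, width=width, height=height,
        )

    sigma1 = np.linalg.norm(A, 2)
    mu = mu0_factor / sigma1
    mu_max = mu_max_factor * mu
    # Standard inexact-ALM warm start for the multiplier.
    Y = A / max(sigma1, np.abs(A).max() / lam)
    L = np.zeros_like(A)
    S = np.zeros_like(A)

    history: list[dict[str, float]] = []
    converged = False
    residual = np.inf
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(A - S + Y / mu, full_matrices=False)
        s_shrunk = np.maximum(s - 1.0 / mu, 0.0)
        L = (U * s_shrunk[np.newaxis, :]) @ Vt
        S = soft_threshold(A - L + Y / mu, lam / mu)
        R = A - L - S
        Y = Y + mu * R
        residual = np.linalg.norm(R) / norm_A
        history.append(
            {
                "residual": float(residual),
                "nuclear_norm": float(s_shrunk.sum()),
                "sparsity_norm": float(np.abs(S).sum()),
                "rank": int(np.count_nonzero(s_shrunk > 1e-10 * max(s_shrunk.max(), 1e-300))),
                "mu": float(mu),
            }
        )
        mu = min(rho * mu, mu_max)
        if residual <= tol:
            converged = True
            break

    return DecompositionResult(
        L=L, S=S, Y=Y, mu=float(mu), converged=converged,
        residual=float(residual), history=history,
        width=width, height=height,
    )
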