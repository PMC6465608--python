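"""Affine image warping and its linearization.

The solver aligns the stack by composing each observation with an affine
map ``tau_i`` and linearizing ``A o (tau + dtau) ~ A o tau + J_i dtau_i``
around the current estimate.  Everything here serves that linearization:

* :func:`affine_warp` -- bilinear warp with parameters
  ``tau = (a11, a12, tx, a21, a22, ty)``, acting in pixel-center
  coordinates with the origin at the image center (rotations are about
  the center).  Output pixel ``x`` samples the input at ``M_tau x``
  (output-to-input mapping); out-of-range samples replicate the border.
* :func:`image_jacobian` -- the ``m x 6`` derivative of the vectorized
  warp with respect to ``tau``.  The spatial gradients used are the exact
  derivatives of the bilinear interpolant (in-cell differences, central
  averaging exactly on grid lines), so the Jacobian agrees with finite
  differences of the implemented warp to interpolation precision.
* :func:`update_transform_increment` -- the closed-form least-squares
  step ``dtau_i = pinv(J_i) (L + S - A o tau - Y/mu) e_i``.
* :func:`normalize_columns` -- rescales each warped column to unit l2
  norm (removing the trivial global-brightness solution) and applies the
  corresponding correction ``(I - a a^T) J / ||a||`` to the Jacobians.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "affine_warp",
    "warp_mask",
    "image_jacobian",
    "update_transform_increment",
    "normalize_columns",
    "compose_transforms",
    "invert_transform",
    "params_to_matrix",
    "matrix_to_params",
]

#: Identity affine parameters (a11, a12, tx, a21, a22, ty).
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])

N_PARAMS = 6


def params_to_matrix(tau: np.ndarray) -> np.ndarray:
    """3x3 homogeneous matrix of ``tau`` in centered pixel coordinates."""
    a11, a12, tx, a21, a22, ty = np.asarray(tau, dtype=float)
    return np.array([[a11, a12, tx], [a21, a22, ty], [0.0, 0.0, 1.0]])


def matrix_to_params(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    return np.array([M[0, 0], M[0, 1], M[0, 2], M[1, 0], M[1, 1], M[1, 2]])


def _check_tau(tau: np.ndarray) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (N_PARAMS,):
        raise ValueError(f"tau must have {N_PARAMS} parameters, got shape {tau.shape}")
    det = tau[0] * tau[4] - tau[1] * tau[3]
    if abs(det) < 1e-8:
        raise ValueError(f"singular linear part (|det| = {abs(det):.2e})")
    return tau


def _source_coords(shape: tuple[int, int], tau: np.ndarray):
    """Sampling coordinates (ys, xs) and centered output grids (u, v)."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    v, u = np.meshgrid(np.arange(h) - cy, np.arange(w) - cx, indexing="ij")
    a11, a12, tx, a21, a22, ty = tau
    xs = a11 * u + a12 * v + tx + cx
    ys = a21 * u + a22 * v + ty + cy
    return ys, xs, u, v


def _bilinear(image: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Bilinear sampling with border replication (coordinate clamping)."""
    h, w = image.shape
    ysc = np.clip(ys, 0.0, h - 1.0)
    xsc = np.clip(xs, 0.0, w - 1.0)
    y0 = np.minimum(np.floor(ysc), h - 2).astype(np.intp) if h > 1 else np.zeros_like(ysc, np.intp)
    x0 = np.minimum(np.floor(xsc), w - 2).astype(np.intp) if w > 1 else np.zeros_like(xsc, np.intp)
    fy = ysc - y0
    fx = xsc - x0
    i00 = image[y0, x0]
    i01 = image[y0, x0 + 1] if w > 1 else i00
    i10 = image[y0 + 1, x0] if h > 1 else i00
    i11 = image[y0 + 1, x0 + 1] if (h > 1 and w > 1) else i00
    return (
        (1 - fy) * ((1 - fx) * i00 + fx * i01)
        + fy * ((1 - fx) * i10 + fx * i11)
    )


def affine_warp(image: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Warp ``image`` by the affine parameters ``tau``.

    Bilinear interpolation, border replication; see module docstring for
    the coordinate convention.
    """
    tau = _check_tau(tau)
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite entries")
    ys, xs, _, _ = _source_coords(image.shape, tau)
    return _bilinear(image, ys, xs)


def warp_mask(mask: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Nearest-neighbour warp of a binary mask."""
    tau = _check_tau(tau)
    mask = np.asarray(mask)
    h, w = mask.shape
    ys, xs, _, _ = _source_coords(mask.shape, tau)
    yi = np.clip(np.rint(ys), 0, h - 1).astype(np.intp)
    xi = np.clip(np.rint(xs), 0, w - 1).astype(np.intp)
    return mask[yi, xi]


def _interpolant_gradients(image: np.ndarray, ys: np.ndarray, xs: np.ndarray):
    """Exact spatial gradients of the bilinear interpolant at (ys, xs).

    Inside a cell the interpolant's x-derivative is the in-cell forward
    difference, linear in y (and symmetrically for the y-derivative).
    Exactly on a grid line the derivative is set to the average of the
    adjacent cell slopes, which is what a centered finite difference of
    the warp measures there.  Samples clamped at the border have zero
    derivative with respect to the clamped coordinate.
    """
    h, w = image.shape
    ysc = np.clip(ys, 0.0, h - 1.0)
    xsc = np.clip(xs, 0.0, w - 1.0)
    y0 = np.minimum(np.floor(ysc), max(h - 2, 0)).astype(np.intp)
    x0 = np.minimum(np.floor(xsc), max(w - 2, 0)).astype(np.intp)
    fy = ysc - y0
    fx = xsc - x0

    if w > 1:
        dx = np.diff(image, axis=1)  # (h, w-1): slope of cell [x, x+1]
        gx0 = dx[y0, x0]
        gx1 = dx[np.minimum(y0 + 1, h - 1), x0]
        gx = (1 - fy) * gx0 + fy * gx1
        # on a vertical grid line, average the two adjacent cell slopes
        on_line = (fx == 0) & (xsc > 0) & (xsc < w - 1)
        if np.any(on_line):
            gxl0 = dx[y0, np.maximum(x0 - 1, 0)]
            gxl1 = dx[np.minimum(y0 + 1, h - 1), np.maximum(x0 - 1, 0)]
            gxl = (1 - fy) * gxl0 + fy * gxl1
            gx = np.where(on_line, 0.5 * (gx + gxl), gx)
        gx = np.where((xs < 0) | (xs > w - 1), 0.0, gx)
    else:
        gx = np.zeros_like(xsc)

    if h > 1:
        dy = np.diff(image, axis=0)  # (h-1, w)
        gy0 = dy[y0, x0]
        gy1 = dy[y0, np.minimum(x0 + 1, w - 1)]
        gy = (1 - fx) * gy0 + fx * gy1
        on_line = (fy == 0) & (ysc > 0) & (ysc < h - 1)
        if np.any(on_line):
            gyl0 = dy[np.maximum(y0 - 1, 0), x0]
            gyl1 = dy[np.maximum(y0 - 1, 0), np.minimum(x0 + 1, w - 1)]
            gyl = (1 - fx) * gyl0 + fx * gyl1
            gy = np.where(on_line, 0.5 * (gy + gyl), gy)
        gy = np.where((ys < 0) | (ys > h - 1), 0.0, gy)
    else:
        gy = np.zeros_like(ysc)
    return gx, gy


def image_jacobian(image: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Derivative of ``vec(affine_warp(image, tau))`` with respect to ``tau``.

    Chain rule: the sampled spatial gradients of the interpolant times the
    derivative of the source coordinates with respect to each parameter.
    Columns follow the parameter order ``(a11, a12, tx, a21, a22, ty)``;
    rows follow the row-major flattening of the image.  Shape ``(m, 6)``.
    """
    tau = _check_tau(tau)
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite entries")
    ys, xs, u, v = _source_coords(image.shape, tau)
    gx, gy = _interpolant_gradients(image, ys, xs)
    J = np.stack(
        [gx * u, gx * v, gx, gy * u, gy * v, gy], axis=-1
    ).reshape(-1, N_PARAMS)
    return J


def update_transform_increment(
    L: np.ndarray,
    S: np.ndarray,
    A_warped: np.ndarray,
    Y: np.ndarray,
    mu: float,
    jacobians: list[np.ndarray],
    pinvs: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Closed-form transform increment ``dtau``, one column per image.

    ``dtau[:, i] = pinv(J_i) @ (L + S - A_warped - Y/mu)[:, i]`` -- the
    least-squares parameter step that best explains the current constraint
    residual through the linearized warp.  Precomputed pseudoinverses can
    be supplied (they are constant within an inner ALM loop).
    """
    for name, M in (("L", L), ("S", S), ("A_warped", A_warped), ("Y", Y)):
        if M.shape != A_warped.shape:
            raise ValueError(f"{name} has shape {M.shape}, expected {A_warped.shape}")
    n = A_warped.shape[1]
    if len(jacobians) != n:
        raise ValueError(f"{len(jacobians)} Jacobians for {n} images")
    R = L + S - A_warped - Y / mu
    dtau = np.empty((N_PARAMS, n))
    if pinvs is None:
        pinvs = [np.linalg.pinv(J) for J in jacobians]
    for i in range(n):
        dtau[:, i] = pinvs[i] @ R[:, i]
    return dtau


def normalize_columns(
    A_warped: np.ndarray, jacobians: list[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Scale warped columns to unit l2 norm, correcting the Jacobians.

    Returns ``(A_normalized, jacobians_corrected, norms)``.  The corrected
    Jacobian is the derivative of the normalized warp:
    ``d(a/||a||) = (I - aa^T/||a||^2) da / ||a||``, i.e. the component of
    ``J`` along the column is projected out before rescaling.
    """
    norms = np.linalg.norm(A_warped, axis=0)
    for i, nrm in enumerate(norms):
        if nrm == 0:
            raise ValueError(f"image {i} is identically zero; cannot normalize")
    A_n = A_warped / norms[np.newaxis, :]
    corrected = []
    for i, J in enumerate(jacobians):
        a = A_n[:, i]
        corrected.append((J - np.outer(a, a @ J)) / norms[i])
    return A_n, corrected, norms


def compose_transforms(tau_a: np.ndarray, tau_b: np.ndarray) -> np.ndarray:
    """Parameters of the composition: warping by the result equals
    warping first by ``tau_a`` then by ``tau_b``.

    With the output-to-input convention, ``warp(warp(I, a), b)`` samples
    ``I`` at ``M_a M_b x``, so the composed matrix is ``M_a @ M_b``.
    """
    return matrix_to_params(
        params_to_matrix(tau_a) @ params_to_matrix(tau_b)
    )


def invert_transform(tau: np.ndarray) -> np.ndarray:
    """Parameters of the inverse affine map."""
    tau = _check_tau(tau)
    return matrix_to_params(np.linalg.inv(params_to_matrix(tau)))
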