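"""Transformed low-rank + structured-sparse decomposition (TLS2D).

Solves

    min_{L,S,tau}  ||L||_*  +  Omega_w(S)    s.t.  A o tau = L + S

where ``A o tau`` warps each observed image by its own affine map,
``Omega_w`` is the (optionally adaptively weighted) overlapping-group
sparsity norm, and the weights default to the uniform ``lam``.  The
nonconvex warp is handled RASL-style: an outer loop linearizes
``A o (tau + dtau) ~ A o tau + sum_i J_i dtau_i e_i^T`` at the current
``tau`` and an inner augmented-Lagrangian loop solves the resulting
convex program by alternating

    L-step:    L = SVT(A o tau + J dtau - S + Y/mu, 1/mu)
    S-step:    S = prox_Omega(A o tau + J dtau - L + Y/mu; mu)
    dtau-step: dtau_i = pinv(J_i) (L + S - A o tau - Y/mu)_i
    Y-step:    Y += mu * h,   mu <- min(rho mu, mu_max)

with ``h = A o tau + J dtau - L - S`` the linearized constraint
residual.  After the inner loop converges, ``tau += dtau`` and the warp
is re-linearized; the outer loop stops when ``||dtau||_F`` is small.

Warped columns are rescaled to unit l2 norm while solving (with the
matching Jacobian correction) to remove the trivial brightness solution;
results carry the norms so images can be mapped back to intensity units.

The two-pass pipeline (:func:`recover_and_segment`) runs the uniform
solve, binarizes the sparse component, multiplies it by an image-saliency
map to get a tumor probability map ``P``, and re-solves with the adaptive
weights ``lam * (1 - P)`` so the sparse component absorbs the lesion
fully while normal regions stay strongly penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Sequence

import numpy as np

from .alignment import (
    IDENTITY,
    affine_warp,
    image_jacobian,
    invert_transform,
    normalize_columns,
    warp_mask,
)
from .lsd import DecompositionResult, ImageStack, default_lambda
from .saliency import SaliencyParams, compute_saliency, tumor_probability
from .structured import (
    GroupStructure,
    ProxState,
    WeightMap,
    binarize_sparse,
    build_groups,
    omega_norm,
    prox_structured,
    singleton_groups,
)

__all__ = [
    "SolverOptions",
    "tls2d_solve",
    "adaptive_tls2d",
    "RecoveryResult",
    "recover_and_segment",
]


@dataclass(frozen=True)
class SolverOptions:
    """Knobs of the TLS2D solver.

    ``lam="auto"`` resolves to ``1/sqrt(max(m, n))`` (in the
    column-normalized space when normalization is on).  ``normalize=None``
    follows ``align``.  ``group_kind`` is ``"3x3"`` (structured sparsity)
    or ``"singleton"`` (plain l1; with alignment off this reduces the
    solver to classical RPCA).
    """

    lam: float | str = "auto"
    outer_max: int = 10
    inner_max: int = 200
    tol_inner: float = 1e-7
    tol_outer: float = 1e-4
    mu0_factor: float = 1.25
    rho: float = 1.25
    mu_max_factor: float = 1e7
    align: bool = True
    normalize: bool | None = None
    group_kind: str = "3x3"
    prox_tol: float = 1e-6
    prox_max_passes: int = 3000
    init_transforms: np.ndarray | None = None
    seed: int | None = None

    def validate(self) -> None:
        for name in ("tol_inner", "tol_outer", "prox_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.outer_max < 1 or self.inner_max < 1:
            raise ValueError("outer_max and inner_max must be at least 1")
        if self.group_kind not in ("3x3", "singleton"):
            raise ValueError(f"unknown group_kind {self.group_kind!r}")
        if not isinstance(self.lam, str) and self.lam <= 0:
            raise ValueError("lam must be positive")

    @property
    def do_normalize(self) -> bool:
        return self.align if self.normalize is None else self.normalize


def _as_stack(A) -> ImageStack:
    if isinstance(A, ImageStack):
        return A
    if isinstance(A, np.ndarray) and A.ndim == 3:
        return ImageStack.from_images(list(A))
    if isinstance(A, (list, tuple)):
        return ImageStack.from_images(A)
    raise TypeError(
        "expected an ImageStack, an (n, h, w) array, or a list of images"
    )


def _resolve_lambda(options: SolverOptions, m: int, n: int) -> float:
    if isinstance(options.lam, str):
        if options.lam != "auto":
            raise ValueError(f"unknown lam setting {options.lam!r}")
        return default_lambda(m, n)
    return float(options.lam)


def tls2d_solve(
    A: ImageStack | np.ndarray | Sequence[np.ndarray],
    weights: WeightMap | None = None,
    options: SolverOptions | None = None,
) -> DecompositionResult:
    """Run the full transformed decomposition (module docstring).

    Parameters
    ----------
    A
        Image stack; at least 3 images of identical size.
    weights
        Sparsity :class:`~tls2d.structured.WeightMap`; ``None`` means the
        uniform penalty ``lam``.
    options
        :class:`SolverOptions`; defaults are suitable for 64x64 phantoms.

    Returns a :class:`~tls2d.lsd.DecompositionResult` whose ``L``, ``S``,
    ``Y`` live in the solving (normalized) space; ``residual`` and
    ``converged`` refer to the linearized constraint the final inner loop
    enforced.  ``transforms`` holds the estimated per-image affine
    parameters, one row per image.
    """
    if options is None:
        options = SolverOptions()
    options.validate()
    stack = _as_stack(A)
    if stack.n < 3:
        raise ValueError(f"at least 3 images required, got {stack.n}")
    m, n = stack.m, stack.n
    w, h = stack.width, stack.height

    if options.group_kind == "singleton":
        groups = singleton_groups(w, h)
    else:
        groups = build_groups(w, h)
    lam = _resolve_lambda(options, m, n)
    if weights is None:
        weights = WeightMap.constant(lam)
    group_w = weights.group_weights(groups, n)

    if options.init_transforms is not None:
        tau = np.array(options.init_transforms, dtype=float, copy=True)
        if tau.shape != (n, 6):
            raise ValueError(f"init_transforms must be (n, 6), got {tau.shape}")
    else:
        tau = np.tile(IDENTITY, (n, 1))

    images = stack.to_images()
    history: list[dict[str, float]] = []
    # dual warm start carried across inner and outer iterations
    prox_state = ProxState.empty(groups, n)
    L = S = Y = None
    A_w = None
    norms = None
    mu = 1.0
    inner_converged = False
    residual = np.inf
    outer_iters = 0
    dtau_norm = np.inf

    for outer in range(options.outer_max):
        outer_iters = outer + 1
        if options.align:
            A_w = np.column_stack(
                [affine_warp(images[i], tau[i]).ravel() for i in range(n)]
            )
            jacobians = [
                image_jacobian(images[i], tau[i]) for i in range(n)
            ]
        else:
            A_w = stack.data.copy()
            jacobians = None
        if options.do_normalize:
            if jacobians is None:
                jacobians_n: list[np.ndarray] | None = None
                norms = np.linalg.norm(A_w, axis=0)
                if np.any(norms == 0):
                    raise ValueError("zero column in observation matrix")
                A_w = A_w / norms[np.newaxis, :]
            else:
                A_w, jacobians_n, norms = normalize_columns(A_w, jacobians)
        else:
            jacobians_n = jacobians
            norms = None
        pinvs = (
            [np.linalg.pinv(J) for J in jacobians_n]
            if (options.align and jacobians_n is not None)
            else None
        )

        norm_Aw = np.linalg.norm(A_w)
        sigma1 = np.linalg.norm(A_w, 2)
        if sigma1 == 0 and outer == 0:
            L = np.zeros_like(A_w)
            S = np.zeros_like(A_w)
            Y = np.zeros_like(A_w)
            inner_converged = True
            residual = 0.0
            history.append(
                {"outer": outer, "inner": 0, "residual": 0.0,
                 "nuclear_norm": 0.0, "omega": 0.0, "rank": 0,
                 "mu": 1.0, "dtau_norm": 0.0}
            )
            break
        if outer == 0:
            mu = options.mu0_factor / sigma1
            mu_max = options.mu_max_factor * mu
            Y = A_w / max(sigma1, np.abs(A_w).max() / lam)
            L = np.zeros_like(A_w)
            S = np.zeros_like(A_w)
        else:
            # warm restart of the ALM after re-linearizing the warp: keep
            # L, S, Y (the constraint moved only slightly) and back the
            # penalty off a few schedule steps so the multiplier can adapt
            mu = max(options.mu0_factor / sigma1, mu / options.rho**8)
        dtau = np.zeros((6, n))
        Jdtau = np.zeros_like(A_w)

        inner_converged = False
        for t in range(options.inner_max):
            B = A_w + Jdtau
            U, sv, Vt = np.linalg.svd(B - S + Y / mu, full_matrices=False)
            sv_shrunk = np.maximum(sv - 1.0 / mu, 0.0)
            L = (U * sv_shrunk[np.newaxis, :]) @ Vt
            # inexact inner solves: the prox only needs to be accurate
            # relative to the current constraint residual; the tolerance
            # tightens to prox_tol as the ALM converges
            prox_tol_t = float(
                np.clip(0.1 * residual, options.prox_tol, 1e-3)
            ) if np.isfinite(residual) else 1e-3
            S = prox_structured(
                B - L + Y / mu, groups, group_w, mu,
                tol=prox_tol_t, max_passes=options.prox_max_passes,
                state=prox_state,
            )
            if options.align:
                R0 = L + S - A_w - Y / mu
                for i in range(n):
                    dtau[:, i] = pinvs[i] @ R0[:, i]
                Jdtau = np.column_stack(
                    [jacobians_n[i] @ dtau[:, i] for i in range(n)]
                )
            hmat = A_w + Jdtau - L - S
            Y = Y + mu * hmat
            residual = float(np.linalg.norm(hmat) / norm_Aw)
            if not np.isfinite(residual):
                raise RuntimeError(
                    f"non-finite residual at outer {outer}, inner {t}"
                )
            history.append(
                {
                    "outer": outer,
                    "inner": t,
                    "residual": residual,
                    "nuclear_norm": float(sv_shrunk.sum()),
                    "omega": float(omega_norm(S, groups, group_w)),
                    "rank": int(np.count_nonzero(
                        sv_shrunk > 1e-10 * max(sv_shrunk.max(), 1e-300)
                    )),
                    "mu": float(mu),
                    "dtau_norm": float(np.linalg.norm(dtau)),
                }
            )
            mu = min(options.rho * mu, mu_max)
            if residual <= options.tol_inner:
                inner_converged = True
                break

        if not options.align:
            dtau_norm = 0.0
            break
        tau = tau + dtau.T
        dtau_norm = float(np.linalg.norm(dtau))
        if dtau_norm <= options.tol_outer:
            break

    return DecompositionResult(
        L=L,
        S=S,
        Y=Y,
        mu=float(mu),
        converged=bool(inner_converged),
        residual=float(residual),
        history=history,
        transforms=tau,
        column_norms=norms,
        constraint_matrix=A_w,
        width=w,
        height=h,
        extra={
            "lambda": lam,
            "outer_iterations": outer_iters,
            "final_dtau_norm": dtau_norm,
            "outer_converged": bool(
                (not options.align) or dtau_norm <= options.tol_outer
            ),
            "group_kind": groups.kind,
        },
    )


def adaptive_tls2d(
    A: ImageStack | np.ndarray | Sequence[np.ndarray],
    P: np.ndarray,
    lam: float | None = None,
    options: SolverOptions | None = None,
) -> DecompositionResult:
    """TLS2D with the adaptive regularizing matrix ``lam * (1 - P)``.

    ``P`` is the per-pixel tumor probability map, shape ``(m, n)`` with
    entries in [0, 1].  ``P = 0`` everywhere reproduces the plain solve
    exactly; where ``P = 1`` the sparsity penalty vanishes and the sparse
    component is free to absorb the whole local residual.
    """
    if options is None:
        options = SolverOptions()
    stack = _as_stack(A)
    P = np.asarray(P, dtype=float)
    if P.shape != stack.data.shape:
        raise ValueError(
            f"P has shape {P.shape}, expected {stack.data.shape}"
        )
    if P.min() < 0 or P.max() > 1:
        raise ValueError("P entries must lie in [0, 1]")
    if lam is None:
        lam = _resolve_lambda(options, stack.m, stack.n)
    weights = WeightMap.from_probability(lam, P)
    options = replace(options, lam=lam)
    return tls2d_solve(stack, weights=weights, options=options)


@dataclass
class RecoveryResult:
    """Output of the two-pass recovery + segmentation pipeline.

    All per-image outputs are in each image's original (unwarped) frame:
    ``recovered`` the quasi-normal reconstructions, ``masks`` the binary
    lesion segmentations, ``probability_maps`` the tumor probability maps
    that drove the adaptive pass.  ``transforms`` are the estimated
    per-image affine parameters; ``pass1``/``pass2`` the full
    decomposition results of the uniform and adaptive solves.
    """

    recovered: np.ndarray  # (n, h, w)
    masks: np.ndarray  # (n, h, w) bool
    probability_maps: np.ndarray  # (n, h, w)
    transforms: np.ndarray  # (n, 6)
    pass1: DecompositionResult
    pass2: DecompositionResult
    extra: dict = field(default_factory=dict)


def recover_and_segment(
    images: ImageStack | np.ndarray | Sequence[np.ndarray],
    options: SolverOptions | None = None,
    saliency_params: SaliencyParams | None = None,
    binarize_method: str = "otsu",
    binarize_floor: float = 0.05,
) -> RecoveryResult:
    """Two-pass pipeline: uniform solve, probability map, adaptive solve.

    Pass 1 aligns and decomposes with the uniform penalty.  Each aligned
    sparse image is binarized and multiplied by the saliency map of the
    corresponding aligned observation, giving the tumor probability map
    ``P``.  Pass 2 re-solves with weights ``lam * (1 - P)`` (warm-started
    at the pass-1 transforms).  Final masks, probability maps and
    recovered images are resampled back to each image's original frame.
    """
    if options is None:
        options = SolverOptions()
    stack = _as_stack(images)
    if stack.n < 3:
        raise ValueError(f"at least 3 images required, got {stack.n}")
    h, w = stack.height, stack.width
    if saliency_params is None:
        saliency_params = SaliencyParams()

    pass1 = tls2d_solve(stack, options=options)
    S1 = pass1.denormalized(pass1.S)
    A_w1 = pass1.denormalized(pass1.constraint_matrix)

    P = np.zeros_like(stack.data)
    for i in range(stack.n):
        s_img = S1[:, i].reshape(h, w)
        mask1 = binarize_sparse(
            s_img, method=binarize_method, floor=binarize_floor
        )
        if mask1.any():
            sal = compute_saliency(A_w1[:, i].reshape(h, w), saliency_params)
            P[:, i] = tumor_probability(mask1, sal).ravel()

    lam = pass1.extra["lambda"]
    options2 = replace(options, init_transforms=pass1.transforms)
    pass2 = adaptive_tls2d(stack, P, lam=lam, options=options2)

    S2 = pass2.denormalized(pass2.S)
    L2 = pass2.denormalized(pass2.L)
    tau = pass2.transforms
    recovered = np.empty((stack.n, h, w))
    masks = np.zeros((stack.n, h, w), dtype=bool)
    prob_maps = np.zeros((stack.n, h, w))
    for i in range(stack.n):
        inv = invert_transform(tau[i])
        mask_aligned = binarize_sparse(
            S2[:, i].reshape(h, w), method=binarize_method,
            floor=binarize_floor,
        )
        masks[i] = warp_mask(mask_aligned, inv)
        recovered[i] = np.clip(
            affine_warp(L2[:, i].reshape(h, w), inv), 0.0, 1.0
        )
        prob_maps[i] = affine_warp(P[:, i].reshape(h, w), inv)

    return RecoveryResult(
        recovered=recovered,
        masks=masks,
        probability_maps=prob_maps,
        transforms=tau,
        pass1=pass1,
        pass2=pass2,
        extra={"lambda": lam},
    )
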