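"""Model / results interface over the decomposition solvers.

Mirrors the fit-centric convention of statistical modelling packages: a
model object is built from data, ``fit()`` runs the estimation and
returns a results object carrying the estimates, diagnostics and a
``summary()`` table; simulation and plotting hang off those objects.

    >>> from tls2d import TLS2D, generate_phantom, PhantomConfig
    >>> truth = generate_phantom(PhantomConfig(seed=7))
    >>> model = TLS2D(truth.observed_images)
    >>> res = model.fit_two_pass()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lsd import DecompositionResult, ImageStack, rpca_alm
from .metrics import SSIMParams, dice, ssim
from .phantom import PhantomTruth
from .saliency import SaliencyParams
from .solver import (
    RecoveryResult,
    SolverOptions,
    _as_stack,
    recover_and_segment,
    tls2d_solve,
)
from .structured import WeightMap, binarize_sparse

__all__ = ["TLS2D", "RPCA", "TLS2DResults", "RPCAResults"]


def _fmt_row(label: str, value) -> str:
    return f"{label:<32s} {value}"


class RPCA:
    """Classical robust PCA model for an image stack (or raw matrix).

    The baseline decomposition ``A = L + S`` with an elementwise-sparse
    ``S``: no alignment, no structured sparsity.
    """

    def __init__(self, data, lam: float | None = None):
        try:
            self.stack: ImageStack | None = _as_stack(data)
            self.data = self.stack.data
        except TypeError:
            self.stack = None
            self.data = np.asarray(data, dtype=float)
        self.lam = lam

    def fit(self, tol: float = 1e-7, max_iter: int = 500) -> "RPCAResults":
        source = self.stack if self.stack is not None else self.data
        result = rpca_alm(source, lam=self.lam, tol=tol, max_iter=max_iter)
        return RPCAResults(model=self, result=result)


@dataclass
class RPCAResults:
    model: RPCA
    result: DecompositionResult

    @property
    def L(self) -> np.ndarray:
        return self.result.L

    @property
    def S(self) -> np.ndarray:
        return self.result.S

    def masks(self, floor: float = 0.05, method: str = "otsu") -> np.ndarray:
        """Binarized sparse component, one boolean image per column."""
        if self.result.width is None:
            raise ValueError("results carry no image geometry")
        h, w = self.result.height, self.result.width
        return np.stack(
            [
                binarize_sparse(
                    self.S[:, i].reshape(h, w), method=method, floor=floor
                )
                for i in range(self.S.shape[1])
            ]
        )

    def summary(self) -> str:
        r = self.result
        last = r.history[-1] if r.history else {}
        lines = [
            "Robust PCA decomposition (inexact ALM)",
            "=" * 46,
            _fmt_row("observations (m x n)", f"{r.L.shape[0]} x {r.L.shape[1]}"),
            _fmt_row("iterations", r.n_iterations),
            _fmt_row("converged", r.converged),
            _fmt_row("relative residual", f"{r.residual:.3e}"),
            _fmt_row("rank(L)", last.get("rank", "n/a")),
            _fmt_row("nuclear norm ||L||_*", f"{last.get('nuclear_norm', float('nan')):.4f}"),
            _fmt_row("l1 norm ||S||_1", f"{last.get('sparsity_norm', float('nan')):.4f}"),
        ]
        return "\n".join(lines)


class TLS2D:
    """Transformed low-rank + structured-sparse decomposition model.

    Built from a stack of >= 3 equal-size grayscale images in [0, 1].
    ``fit()`` runs a single decomposition (optionally with an adaptive
    weight map); ``fit_two_pass()`` runs the full recovery/segmentation
    pipeline (uniform pass, saliency-derived probability map, adaptive
    pass).
    """

    def __init__(self, images, options: SolverOptions | None = None, **kwargs):
        self.stack = _as_stack(images)
        if options is None:
            options = SolverOptions(**kwargs)
        elif kwargs:
            raise TypeError("pass either options or keyword overrides, not both")
        self.options = options

    @classmethod
    def from_directory(cls, path, **kwargs) -> "TLS2D":
        from .io import read_stack

        return cls(read_stack(path), **kwargs)

    def fit(self, weights: WeightMap | None = None) -> "TLS2DResults":
        result = tls2d_solve(self.stack, weights=weights, options=self.options)
        return TLS2DResults(model=self, result=result, recovery=None)

    def fit_two_pass(
        self,
        saliency_params: SaliencyParams | None = None,
        binarize_method: str = "otsu",
        binarize_floor: float = 0.05,
    ) -> "TLS2DResults":
        recovery = recover_and_segment(
            self.stack,
            options=self.options,
            saliency_params=saliency_params,
            binarize_method=binarize_method,
            binarize_floor=binarize_floor,
        )
        return TLS2DResults(
            model=self, result=recovery.pass2, recovery=recovery
        )


@dataclass
class TLS2DResults:
    """Estimates and diagnostics of a TLS2D fit.

    ``result`` is the decomposition of the (final) solve; ``recovery`` is
    populated by :meth:`TLS2D.fit_two_pass` and carries the per-image
    recovered images, masks and probability maps in the original frames.
    """

    model: TLS2D
    result: DecompositionResult
    recovery: RecoveryResult | None = None

    @property
    def transforms(self) -> np.ndarray:
        return self.result.transforms

    def low_rank_images(self) -> list[np.ndarray]:
        return self.result.low_rank_images()

    def sparse_images(self) -> list[np.ndarray]:
        return self.result.sparse_images()

    def recovered_images(self) -> np.ndarray:
        if self.recovery is None:
            raise ValueError("run fit_two_pass() for recovered images")
        return self.recovery.recovered

    def tumor_masks(self) -> np.ndarray:
        if self.recovery is None:
            raise ValueError("run fit_two_pass() for tumor masks")
        return self.recovery.masks

    def evaluate(
        self, truth: PhantomTruth, ssim_params: SSIMParams | None = None
    ) -> dict:
        """Dice/SSIM against planted phantom truth (original frames)."""
        if self.recovery is None:
            raise ValueError("run fit_two_pass() before evaluating")
        if ssim_params is None:
            ssim_params = SSIMParams()
        n = truth.n_images
        dices = [
            dice(self.recovery.masks[i], truth.tumor_masks[i])
            for i in range(n)
        ]
        ssims = [
            ssim(self.recovery.recovered[i], truth.warped_clean(i), ssim_params)
            for i in range(n)
        ]
        tumor = truth.tumor_indices()
        return {
            "dice": dices,
            "ssim": ssims,
            "mean_dice": float(np.mean(dices)),
            "mean_ssim": float(np.mean(ssims)),
            "mean_dice_tumor": float(np.mean([dices[i] for i in tumor]))
            if len(tumor)
            else 1.0,
            "mean_ssim_tumor": float(np.mean([ssims[i] for i in tumor]))
            if len(tumor)
            else float(np.mean(ssims)),
        }

    def summary(self) -> str:
        r = self.result
        last = r.history[-1] if r.history else {}
        lines = [
            "Transformed low-rank + structured-sparse decomposition",
            "=" * 56,
            _fmt_row("images (n)", r.L.shape[1]),
            _fmt_row("pixels per image (m)", r.L.shape[0]),
            _fmt_row("lambda", f"{r.extra.get('lambda', float('nan')):.5f}"),
            _fmt_row("group structure", r.extra.get("group_kind", "3x3")),
            _fmt_row("outer iterations", r.extra.get("outer_iterations")),
            _fmt_row("total inner iterations", r.n_iterations),
            _fmt_row("converged (inner)", r.converged),
            _fmt_row("outer converged (|dtau|)", r.extra.get("outer_converged")),
            _fmt_row("relative residual", f"{r.residual:.3e}"),
            _fmt_row("rank(L)", last.get("rank", "n/a")),
            _fmt_row("nuclear norm ||L||_*", f"{last.get('nuclear_norm', float('nan')):.4f}"),
            _fmt_row("Omega(S)", f"{last.get('omega', float('nan')):.4f}"),
        ]
        if self.recovery is not None:
            areas = self.recovery.masks.sum(axis=(1, 2))
            lines += [
                "-" * 56,
                _fmt_row("two-pass pipeline", "uniform -> P map -> adaptive"),
                _fmt_row("images with lesions found", int((areas > 0).sum())),
                _fmt_row("mean lesion area (px)",
                         f"{areas[areas > 0].mean():.1f}" if (areas > 0).any() else "0"),
            ]
        return "\n".join(lines)

    def plot_decomposition(self, i: int = 0, ax=None):
        """Observed / low-rank / sparse panels for image ``i``."""
        import matplotlib.pyplot as plt

        r = self.result
        h, w = r.height, r.width
        panels = [
            (r.denormalized(r.constraint_matrix)[:, i].reshape(h, w), "aligned observed"),
            (r.denormalized(r.L)[:, i].reshape(h, w), "low rank L"),
            (np.abs(r.denormalized(r.S))[:, i].reshape(h, w), "|sparse S|"),
        ]
        if self.recovery is not None:
            panels.append((self.recovery.masks[i].astype(float), "mask"))
        if ax is None:
            _, ax = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3))
        for a, (img, title) in zip(np.atleast_1d(ax), panels):
            a.imshow(img, cmap="gray", vmin=0, vmax=max(img.max(), 1e-6))
            a.set_title(title)
            a.axis("off")
        return ax

    def plot_convergence(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = [rec["residual"] for rec in self.result.history]
        ax.semilogy(res)
        ax.set_xlabel("inner iteration")
        ax.set_ylabel("relative residual")
        return ax
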