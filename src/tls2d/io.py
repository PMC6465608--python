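"""Stack readers/writers and the declarative run configuration.

Images are exchanged as grayscale PNG/TIFF files (one image per file,
filename-sorted column order) or as 2-D slices of a NIfTI volume.
Intensities are rescaled to [0, 1] by the format's maximum value.  Every
write produces a ``manifest.json`` recording the file-to-column mapping,
shapes and scales, so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lsd import DecompositionResult, ImageStack
from .metrics import SSIMParams
from .phantom import PhantomConfig
from .saliency import SaliencyParams
from .solver import SolverOptions

__all__ = [
    "read_stack",
    "read_image",
    "write_image",
    "write_stack",
    "RunConfig",
    "load_config",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def _to_unit_interval(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def read_image(path: str | Path) -> np.ndarray:
    """Read one grayscale image, rescaled to [0, 1]."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    return _to_unit_interval(iio.imread(path))


def write_image(path: str | Path, image: np.ndarray, bits: int = 16) -> None:
    """Write a [0, 1] image as 8- or 16-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bits == 16:
        iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))
    elif bits == 8:
        iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))
    else:
        raise ValueError("bits must be 8 or 16")


def read_stack(
    path: str | Path,
    pattern: str | None = None,
    axis: int = 2,
    slices: slice | tuple[int, int] | None = None,
) -> ImageStack:
    """Read an image stack from a directory or a NIfTI volume.

    A directory is scanned for PNG/TIFF files (optionally filtered by a
    glob ``pattern``), sorted by filename; a ``.nii``/``.nii.gz`` path is
    sliced along ``axis`` (optionally restricted to a ``(start, stop)``
    range).  All images must share one size.
    """
    path = Path(path)
    if path.is_dir():
        if pattern is not None:
            files = sorted(path.glob(pattern))
        else:
            files = sorted(
                p for p in path.iterdir()
                if p.suffix.lower() in _IMAGE_SUFFIXES
            )
        if not files:
            raise FileNotFoundError(f"no images found in {path}")
        images = []
        shape = None
        for f in files:
            img = read_image(f)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"{f} has shape {img.shape}, expected {shape} "
                    "(mixed image sizes)"
                )
            images.append(img)
        return ImageStack.from_images(images, names=[f.name for f in files])
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if slices is not None:
            start, stop = (slices.start, slices.stop) if isinstance(
                slices, slice
            ) else slices
            vol = np.take(vol, np.arange(start, stop), axis=axis)
        vmax = vol.max()
        if vmax > 0:
            vol = vol / vmax
        images = [
            np.take(vol, k, axis=axis) for k in range(vol.shape[axis])
        ]
        names = [f"slice_{k:04d}" for k in range(len(images))]
        return ImageStack.from_images(images, names=names)
    raise FileNotFoundError(
        f"{path} is neither a directory nor a NIfTI volume"
    )


def write_stack(
    result: DecompositionResult,
    directory: str | Path,
    masks: np.ndarray | None = None,
    probability_maps: np.ndarray | None = None,
    recovered: np.ndarray | None = None,
) -> dict:
    """Write a decomposition (and optional pipeline outputs) to disk.

    ``L`` columns as 16-bit PNGs; ``S`` as ``|S|`` rescaled by its global
    maximum (scale recorded in the manifest); masks as 8-bit PNGs;
    transforms as text; history as CSV; a manifest JSON listing every
    file with shape metadata.  Returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if result.width is None or result.height is None:
        raise ValueError("result carries no image geometry")
    h, w = result.height, result.width
    n = result.L.shape[1]
    Ld = result.denormalized(result.L)
    Sd = result.denormalized(result.S)
    s_scale = float(np.abs(Sd).max()) or 1.0

    manifest: dict = {
        "n_images": n,
        "width": w,
        "height": h,
        "sparse_scale": s_scale,
        "lambda": result.extra.get("lambda"),
        "converged": result.converged,
        "residual": result.residual,
        "files": [],
    }

    def record(name, kind):
        manifest["files"].append(
            {"name": name, "kind": kind, "shape": [h, w]}
        )

    for i in range(n):
        name = f"L_{i:03d}.png"
        write_image(directory / name, Ld[:, i].reshape(h, w))
        record(name, "low_rank")
        name = f"S_{i:03d}.png"
        write_image(
            directory / name, np.abs(Sd[:, i]).reshape(h, w) / s_scale
        )
        record(name, "sparse_magnitude")
        if masks is not None:
            name = f"mask_{i:03d}.png"
            write_image(directory / name, masks[i].astype(float), bits=8)
            record(name, "mask")
        if probability_maps is not None:
            name = f"P_{i:03d}.png"
            write_image(directory / name, probability_maps[i], bits=8)
            record(name, "probability")
        if recovered is not None:
            name = f"recovered_{i:03d}.png"
            write_image(directory / name, recovered[i])
            record(name, "recovered")

    if result.transforms is not None:
        with open(directory / "transforms.txt", "w") as fh:
            for i in range(n):
                vals = " ".join(f"{v:.17g}" for v in result.transforms[i])
                fh.write(f"tau_{i}: {vals}\n")
        manifest["files"].append(
            {"name": "transforms.txt", "kind": "transforms", "shape": [n, 6]}
        )
    result.history_frame().to_csv(directory / "history.csv", index=False)
    manifest["files"].append(
        {"name": "history.csv", "kind": "history",
         "shape": [len(result.history)]}
    )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# declarative run configuration


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}"
        )
    if "tumor_radius_range" in data:
        data = dict(data)
        data["tumor_radius_range"] = tuple(data["tumor_radius_range"])
    return cls(**data)


@dataclass
class RunConfig:
    """All tunables of a run as one declarative document.

    Sections ``phantom``, ``solver``, ``saliency``, ``ssim`` map onto the
    corresponding parameter dataclasses; ``binarize_method`` and
    ``binarize_floor`` control mask extraction.  Unknown keys are
    rejected; :meth:`resolved` returns the fully defaulted document for
    writing next to the outputs.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    solver: SolverOptions = field(default_factory=SolverOptions)
    saliency: SaliencyParams = field(default_factory=SaliencyParams)
    ssim: SSIMParams = field(default_factory=SSIMParams)
    binarize_method: str = "otsu"
    binarize_floor: float = 0.05

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        sections = {
            "phantom": PhantomConfig,
            "solver": SolverOptions,
            "saliency": SaliencyParams,
            "ssim": SSIMParams,
        }
        kwargs = {}
        for name, scls in sections.items():
            if name in doc:
                kwargs[name] = _build_section(scls, doc.pop(name), name)
        for scalar in ("binarize_method", "binarize_floor"):
            if scalar in doc:
                kwargs[scalar] = doc.pop(scalar)
        if doc:
            raise ValueError(f"unknown config keys: {sorted(doc)}")
        return cls(**kwargs)

    def resolved(self) -> dict:
        out = {
            "phantom": dataclasses.asdict(self.phantom),
            "solver": dataclasses.asdict(self.solver),
            "saliency": dataclasses.asdict(self.saliency),
            "ssim": dataclasses.asdict(self.ssim),
            "binarize_method": self.binarize_method,
            "binarize_floor": self.binarize_floor,
        }
        out["phantom"]["tumor_radius_range"] = list(
            self.phantom.tumor_radius_range
        )
        out["solver"].pop("init_transforms", None)
        return out

    def dump(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=False)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RunConfig.from_dict(doc)
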