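"""Containers and I/O for ion-image datacubes.

An MSI experiment yields one intensity image per m/z feature, all on a
shared pixel raster.  :class:`IonImageStack` holds that datacube — an
``(n, h, w)`` intensity array plus the ``n`` m/z values — and is the
universal input of every operation in this package.  Stacks are stored in
a simple HDF5 container and can also be read from processed (centroided)
imzML files with a common m/z axis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

__all__ = [
    "IonImageStack",
    "FormatError",
    "load_stack",
    "save_stack",
    "normalize_stack",
    "mean_ion_image",
]


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclasses.dataclass
class IonImageStack:
    """A stack of n ion images on a shared h×w pixel grid.

    Parameters
    ----------
    mz
        Mass-to-charge values in Da, strictly increasing, one per image.
    images
        Non-negative intensities, shape ``(n, h, w)``, float32.
    pixel_mask
        Optional ``(h, w)`` boolean array; True marks on-tissue pixels.
    meta
        Free-form provenance (source path, normalization flag, ...).
    """

    mz: np.ndarray
    images: np.ndarray
    pixel_mask: Optional[np.ndarray] = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise FormatError(
                f"images must be (n, h, w), got shape {self.images.shape}"
            )
        n, h, w = self.images.shape
        if self.mz.ndim != 1 or len(self.mz) != n:
            raise FormatError(
                f"mz length {self.mz.size} does not match {n} images"
            )
        if n < 2:
            raise FormatError("a stack needs at least 2 ion images")
        if h < 4 or w < 4:
            raise FormatError(f"image grid {h}x{w} is too small (min 4x4)")
        bad = ~np.isfinite(self.images).all(axis=(1, 2))
        if bad.any():
            raise FormatError(
                f"non-finite intensities in image(s) {np.flatnonzero(bad).tolist()}"
            )
        if not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.images = self.images[order]
            self.meta = dict(self.meta, mz_sort_permutation=order.tolist())
            if not np.all(np.diff(self.mz) > 0):
                raise FormatError("duplicate m/z values in stack")
        if self.pixel_mask is not None:
            self.pixel_mask = np.asarray(self.pixel_mask, dtype=bool)
            if self.pixel_mask.shape != (h, w):
                raise FormatError(
                    f"pixel_mask shape {self.pixel_mask.shape} != image grid {(h, w)}"
                )

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.images.shape

    def flattened(self) -> np.ndarray:
        """Images as an (n, h*w) matrix, the vectorization baselines' view."""
        return self.images.reshape(self.n, -1)


def save_stack(stack: IonImageStack, path) -> Path:
    """Write a stack to an HDF5 container, losslessly.

    Layout: root datasets ``mz`` (float64) and ``images`` (float32),
    optional ``mask`` (uint8), plus ``source``/``normalized`` attributes.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("mz", data=stack.mz.astype(np.float64))
        f.create_dataset("images", data=stack.images.astype(np.float32))
        if stack.pixel_mask is not None:
            f.create_dataset("mask", data=stack.pixel_mask.astype(np.uint8))
        f.attrs["source"] = str(stack.meta.get("source", ""))
        f.attrs["normalized"] = int(bool(stack.meta.get("normalized", False)))
    return path


def load_stack(path, format: Optional[str] = None) -> IonImageStack:
    """Read a stack from HDF5 (``.h5``) or processed imzML (``.imzML``).

    The format is inferred from the suffix when not given.  imzML pixels
    absent from the raster become mask=False with intensity 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "imzml" if path.suffix.lower() == ".imzml" else "hdf5"
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "imzml":
        return _load_imzml(path)
    raise ValueError(f"unknown format {format!r}")


def _load_hdf5(path: Path) -> IonImageStack:
    with h5py.File(path, "r") as f:
        for name in ("mz", "images"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset {name!r}")
        mz = f["mz"][()]
        images = f["images"][()]
        mask = f["mask"][()].astype(bool) if "mask" in f else None
        meta = {
            "source": f.attrs.get("source", str(path)),
            "normalized": bool(f.attrs.get("normalized", 0)),
        }
    return IonImageStack(mz=mz, images=images, pixel_mask=mask, meta=meta)


def _load_imzml(path: Path) -> IonImageStack:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = np.asarray([(x, y) for x, y, _z in parser.coordinates])
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    h, w = int(ymax - ymin + 1), int(xmax - xmin + 1)

    ref_mz, _ = parser.getspectrum(0)
    ref_mz = np.asarray(ref_mz, dtype=np.float64)
    n = len(ref_mz)
    images = np.zeros((n, h, w), dtype=np.float32)
    mask = np.zeros((h, w), dtype=bool)
    for idx in range(len(parser.coordinates)):
        mz, intens = parser.getspectrum(idx)
        mz = np.asarray(mz, dtype=np.float64)
        if len(mz) != n or not np.allclose(mz, ref_mz):
            raise FormatError(
                f"{path}: per-pixel m/z axes are not aligned; bin the file "
                "to a common m/z axis upstream before loading"
            )
        x, y, _z = parser.coordinates[idx]
        r, c = int(y - ymin), int(x - xmin)
        images[:, r, c] = intens
        mask[r, c] = True
    return IonImageStack(
        mz=ref_mz,
        images=images,
        pixel_mask=mask,
        meta={"source": str(path), "normalized": False},
    )


def normalize_stack(stack: IonImageStack) -> IonImageStack:
    """Min-max scale every ion image to [0, 1] independently.

    Masked-off pixels are zeroed before scaling.  A constant image carries
    no spatial information and maps to all-zeros rather than dividing by a
    zero range.  Idempotent.
    """
    images = stack.images.astype(np.float32).copy()
    if stack.pixel_mask is not None:
        images[:, ~stack.pixel_mask] = 0.0
    lo = images.min(axis=(1, 2), keepdims=True)
    hi = images.max(axis=(1, 2), keepdims=True)
    rng = hi - lo
    flat = rng[:, 0, 0] == 0
    rng[flat.reshape(-1, 1, 1)] = 1.0
    out = (images - lo) / rng
    out[flat] = 0.0
    mask = None if stack.pixel_mask is None else stack.pixel_mask.copy()
    return IonImageStack(
        mz=stack.mz.copy(),
        images=out,
        pixel_mask=mask,
        meta=dict(stack.meta, normalized=True),
    )


def mean_ion_image(stack: IonImageStack, indices) -> np.ndarray:
    """Pixel-wise mean image over the selected ion images.

    This is the representative spatial profile of a cluster of ions.
    """
    indices = np.asarray(indices, dtype=np.intp)
    if indices.size == 0:
        raise ValueError("indices must be non-empty")
    if indices.min() < 0 or indices.max() >= stack.n:
        raise IndexError(f"indices out of range [0, {stack.n})")
    return stack.images[indices].mean(axis=0, dtype=np.float64).astype(np.float32)
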