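"""Raster image containers and file I/O.

All images are held internally as unit-range floating-point arrays
(``float64``, intensities in ``[0, 1]``), either single-channel
``(H, W)`` conceptually stored as ``(H, W, 1)``-equivalent 2-D planes or
RGB ``(H, W, 3)``.  Files are read through :mod:`imageio`, which handles
PNG, TIFF and JPEG at 8 and 16 bits; intensities are scaled by
``1 / (2**depth - 1)`` on read and re-quantized on write.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ImageRaster",
    "ImageStack",
    "read_image",
    "write_image",
    "to_single_channel",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The file could not be decoded as a supported raster image."""


class DimensionError(ValueError):
    """Image dimensions violate the minimum 2x2 requirement."""


@dataclass(frozen=True)
class ImageRaster:
    """A single co-registered source (or fused) image.

    Parameters
    ----------
    pixels
        Intensities in ``[0, 1]``; shape ``(H, W)`` for grayscale or
        ``(H, W, 3)`` for RGB.
    source_bit_depth
        Bit depth of the file the raster came from (8 or 16); purely
        informational for rasters built in memory.
    """

    pixels: np.ndarray
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise DimensionError(
                f"expected (H, W) or (H, W, 3) pixel array, got shape {px.shape}"
            )
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise DimensionError(
                f"image must be at least 2x2, got {px.shape[0]}x{px.shape[1]}"
            )
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite intensities")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError(
                f"intensities must lie in [0, 1], got range "
                f"[{px.min():.4g}, {px.max():.4g}]"
            )
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class ImageStack:
    """An ordered collection of K >= 2 co-registered, same-shape images."""

    images: tuple[ImageRaster, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        images = tuple(self.images)
        if len(images) < 2:
            raise ValueError(f"a stack needs at least 2 images, got {len(images)}")
        ref = images[0]
        for k, im in enumerate(images[1:], start=1):
            if im.shape != ref.shape or im.channels != ref.channels:
                raise ValueError(
                    f"image {k} has shape {im.shape}x{im.channels}, "
                    f"expected {ref.shape}x{ref.channels}"
                )
        object.__setattr__(self, "images", images)

    @property
    def K(self) -> int:
        return len(self.images)

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, k: int) -> ImageRaster:
        return self.images[k]

    def __iter__(self):
        return iter(self.images)


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint16:
        return 16
    if arr.dtype == np.uint8:
        return 8
    raise FormatError(f"unsupported sample type {arr.dtype}; expected uint8/uint16")


def read_image(path: str | Path) -> ImageRaster:
    """Read a PNG/TIFF/JPG file into a unit-range :class:`ImageRaster`.

    Palette images are expanded to RGB by the decoder; an alpha channel,
    if present, is dropped with a warning (the fusion pipeline operates
    on intensity data only).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder-specific exception zoo
        raise FormatError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (2, 4):
        warnings.warn(f"{path.name}: dropping alpha channel", stacklevel=2)
        arr = arr[:, :, :-1]
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: unsupported array shape {arr.shape}")
    depth = _bit_depth_of(arr)
    scale = float(2**depth - 1)
    return ImageRaster(arr.astype(np.float64) / scale, source_bit_depth=depth)


def write_image(raster: ImageRaster, path: str | Path, bit_depth: int = 8) -> None:
    """Quantize to ``bit_depth`` and write; round-trip error <= 1 LSB."""
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    scale = float(2**bit_depth - 1)
    quant = np.rint(raster.pixels * scale)
    arr = quant.astype(np.uint8 if bit_depth == 8 else np.uint16)
    try:
        iio.imwrite(path, arr)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def to_single_channel(raster: ImageRaster) -> ImageRaster:
    """Reduce RGB to one channel by the unweighted channel mean.

    Grayscale input is returned unchanged.  The plain mean (rather than
    luma weights) keeps the reduction symmetric in the three channels;
    it only feeds the edge-activity measure, never the fused output.
    """
    if raster.channels == 1:
        return raster
    return ImageRaster(
        raster.pixels.mean(axis=2), source_bit_depth=raster.source_bit_depth
    )
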