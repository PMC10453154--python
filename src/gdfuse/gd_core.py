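"""The Gaussian-of-differences (GD) fusion pipeline.

Fusion proceeds in five pixel-domain steps applied to K co-registered
source images ``I_k``:

1. signed first-order differences along columns and rows,
   ``CD_k(i,j) = I_k(i,j) - I_k(i,j+1)``, ``RD_k(i,j) = I_k(i,j) - I_k(i+1,j)``;
2. a per-pixel edge magnitude ``D_k`` combining the two directions
   (default: Euclidean gradient magnitude);
3. smoothing of ``D_k`` with a ``(2s+1) x (2s+1)`` Gaussian window of
   spread ``sigma``, giving the edge-activity surface ``GD_k``;
4. per-pixel normalization across images,
   ``fw_k = GD_k / sum_k GD_k``, so the K weights sum to one everywhere;
5. linear fusion ``F = sum_k fw_k * I_k``.

The fused intensity is a per-pixel convex combination of the sources, so
it always lies between their per-pixel minimum and maximum.  Because the
weights are a ratio with the same kernel for every image, any positive
rescaling of the kernel leaves the fused image unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .image_io import ImageRaster, ImageStack, to_single_channel

__all__ = [
    "GDConfig",
    "PRESETS",
    "DifferencePair",
    "DifferenceMap",
    "GaussianKernel",
    "SmoothedDifferenceMap",
    "WeightMaps",
    "FusedImage",
    "directional_differences",
    "edge_magnitude",
    "gaussian_kernel",
    "smooth_differences",
    "normalize_weights",
    "fuse",
    "gd_fuse",
]

MagnitudeRule = Literal["euclidean", "sum_abs", "sum_sq"]
BoundaryRule = Literal["replicate", "zero"]

#: Per-pixel activity sums below this fall back to uniform 1/K weights.
ZERO_ACTIVITY_EPS = 1e-12


@dataclass(frozen=True)
class GDConfig:
    """Fusion parameters.

    ``s`` is the half-size of the Gaussian window (side ``2s+1``);
    ``sigma`` is its spread, or ``"auto"`` for the ``s/3`` rule.
    """

    s: int = 10
    sigma: float | Literal["auto"] = "auto"
    magnitude_rule: MagnitudeRule = "euclidean"
    boundary: BoundaryRule = "replicate"

    def __post_init__(self) -> None:
        if int(self.s) != self.s or self.s < 1:
            raise ValueError(f"s must be an integer >= 1, got {self.s}")
        object.__setattr__(self, "s", int(self.s))
        if self.sigma != "auto":
            if not (float(self.sigma) > 0):
                raise ValueError(f"sigma must be positive, got {self.sigma}")
            object.__setattr__(self, "sigma", float(self.sigma))
        if self.magnitude_rule not in ("euclidean", "sum_abs", "sum_sq"):
            raise ValueError(f"unknown magnitude_rule {self.magnitude_rule!r}")
        if self.boundary not in ("replicate", "zero"):
            raise ValueError(f"unknown boundary rule {self.boundary!r}")

    @property
    def effective_sigma(self) -> float:
        """Resolved spread: ``s/3`` when sigma is ``"auto"``."""
        return self.s / 3.0 if self.sigma == "auto" else float(self.sigma)


#: Named presets.  Sigmas are stored as the rounded published values
#: (1.6, 3.3, 5), not recomputed from s/3.
PRESETS: dict[str, GDConfig] = {
    "gd5": GDConfig(s=5, sigma=1.6),
    "gd10": GDConfig(s=10, sigma=3.3),
    "gd15": GDConfig(s=15, sigma=5.0),
}


@dataclass(frozen=True)
class DifferencePair:
    """Signed column and row differences of one image plane."""

    cd: np.ndarray
    rd: np.ndarray

    def __post_init__(self) -> None:
        if self.cd.shape != self.rd.shape:
            raise ValueError("cd and rd must share a shape")


@dataclass(frozen=True)
class DifferenceMap:
    """Non-negative combined edge magnitude D."""

    d: np.ndarray

    def __post_init__(self) -> None:
        if (self.d < 0).any():
            raise ValueError("edge magnitudes must be non-negative")


@dataclass(frozen=True)
class GaussianKernel:
    """A normalized, centrally peaked (2s+1) x (2s+1) Gaussian window."""

    s: int
    sigma: float
    coefficients: np.ndarray


@dataclass(frozen=True)
class SmoothedDifferenceMap:
    """Gaussian-smoothed edge activity GD."""

    gd: np.ndarray


@dataclass(frozen=True)
class WeightMaps:
    """Per-image fusion coefficients; across images they sum to 1 per pixel."""

    fw: np.ndarray  # (K, H, W)

    def __post_init__(self) -> None:
        fw = np.asarray(self.fw, dtype=np.float64)
        if fw.ndim != 3 or fw.shape[0] < 2:
            raise ValueError("weights must be (K>=2, H, W)")
        if fw.min() < -1e-9 or fw.max() > 1 + 1e-9:
            raise ValueError("weights must lie in [0, 1]")
        sums = fw.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("per-pixel weights must sum to 1")
        object.__setattr__(self, "fw", fw)

    @property
    def K(self) -> int:
        return self.fw.shape[0]


@dataclass(frozen=True)
class FusedImage:
    """The fused result F."""

    pixels: ImageRaster


def directional_differences(
    plane: ImageRaster | np.ndarray, boundary: BoundaryRule = "replicate"
) -> DifferencePair:
    """First-order differences of a single-channel plane.

    ``cd(i,j) = I(i,j) - I(i,j+1)`` and ``rd(i,j) = I(i,j) - I(i+1,j)``.
    The last column of ``cd`` (and last row of ``rd``) has no in-image
    neighbor; with the default replicate boundary the missing neighbor
    equals the edge pixel, so the difference is 0.  With ``"zero"`` the
    missing neighbor is 0 and the difference equals the edge intensity.
    """
    if isinstance(plane, ImageRaster):
        if plane.channels != 1:
            raise ValueError("reduce to a single channel first (to_single_channel)")
        arr = plane.pixels
    else:
        arr = np.asarray(plane, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D plane")
    cd = np.zeros_like(arr)
    rd = np.zeros_like(arr)
    cd[:, :-1] = arr[:, :-1] - arr[:, 1:]
    rd[:-1, :] = arr[:-1, :] - arr[1:, :]
    if boundary == "zero":
        cd[:, -1] = arr[:, -1]
        rd[-1, :] = arr[-1, :]
    return DifferencePair(cd=cd, rd=rd)


def edge_magnitude(
    pair: DifferencePair, rule: MagnitudeRule = "euclidean"
) -> DifferenceMap:
    """Combine the directional differences into one non-negative map."""
    cd, rd = pair.cd, pair.rd
    if rule == "euclidean":
        d = np.hypot(cd, rd)
    elif rule == "sum_abs":
        d = np.abs(cd) + np.abs(rd)
    elif rule == "sum_sq":
        d = cd * cd + rd * rd
    else:
        raise ValueError(f"unknown magnitude rule {rule!r}")
    return DifferenceMap(d=d)


def gaussian_kernel(s: int, sigma: float) -> GaussianKernel:
    """Isotropic Gaussian sampled at integer offsets in [-s, s]^2.

    Coefficients are proportional to ``exp(-(x^2 + y^2) / (2 sigma^2))``
    and normalized to unit sum.  Normalization is mathematically
    irrelevant to the fused image (the weight ratio cancels any positive
    scale) but keeps the smoothed activity on the scale of the raw
    edge magnitudes.
    """
    if s < 0 or int(s) != s:
        raise ValueError(f"s must be a non-negative integer, got {s}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    offsets = np.arange(-s, s + 1, dtype=np.float64)
    x, y = np.meshgrid(offsets, offsets)
    coeff = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    coeff /= coeff.sum()
    return GaussianKernel(s=int(s), sigma=float(sigma), coefficients=coeff)


def smooth_differences(
    dmap: DifferenceMap,
    kernel: GaussianKernel,
    boundary: BoundaryRule = "replicate",
) -> SmoothedDifferenceMap:
    """Correlate the edge map with the Gaussian window.

    ``gd(i,j) = sum_{p,r in [-s,s]} w(p,r) d(i+p, j+r)``, out-of-bounds
    neighbors supplied by the boundary rule (default: edge replication).
    """
    d = dmap.d
    if 2 * kernel.s + 1 > 2 * min(d.shape) + 1:
        warnings.warn(
            f"kernel side {2 * kernel.s + 1} exceeds twice the image extent "
            f"{min(d.shape)}; smoothing is effectively global",
            stacklevel=2,
        )
    mode = "nearest" if boundary == "replicate" else "constant"
    gd = ndimage.correlate(d, kernel.coefficients, mode=mode, cval=0.0)
    # correlation of non-negative data with non-negative weights
    return SmoothedDifferenceMap(gd=np.maximum(gd, 0.0))


def normalize_weights(gds: Sequence[SmoothedDifferenceMap]) -> WeightMaps:
    """Per-pixel ratio normalization across the K activity maps.

    Pixels where the total activity is below ``ZERO_ACTIVITY_EPS`` carry
    no preference and fall back to uniform ``1/K`` weights.
    """
    if len(gds) < 2:
        raise ValueError("need at least 2 activity maps")
    shapes = {g.gd.shape for g in gds}
    if len(shapes) != 1:
        raise ValueError(f"activity maps have mismatched shapes: {shapes}")
    stack = np.stack([g.gd for g in gds])
    total = stack.sum(axis=0)
    flat = total < ZERO_ACTIVITY_EPS
    safe_total = np.where(flat, 1.0, total)
    fw = np.where(flat, 1.0 / len(gds), stack / safe_total)
    return WeightMaps(fw=fw)


def fuse(stack: ImageStack, weights: WeightMaps) -> FusedImage:
    """Linear per-pixel blend ``F = sum_k fw_k I_k``.

    For RGB stacks the single weight map of each image is applied to all
    three channels, which keeps the blend consistent across channels and
    avoids color fringing.
    """
    if weights.K != stack.K:
        raise ValueError(f"{stack.K} images but {weights.K} weight maps")
    if weights.fw.shape[1:] != stack[0].shape:
        raise ValueError(
            f"weight shape {weights.fw.shape[1:]} does not match image "
            f"shape {stack[0].shape}"
        )
    fw = weights.fw
    if stack[0].channels == 3:
        fw = fw[:, :, :, None]
    fused = sum(w * im.pixels for w, im in zip(fw, stack))
    # guard against floating-point drift just past the unit range
    fused = np.clip(fused, 0.0, 1.0)
    return FusedImage(pixels=ImageRaster(fused))


def compute_weights(stack: ImageStack, config: GDConfig | None = None) -> WeightMaps:
    """Steps 1-4: per-image edge activity, jointly normalized."""
    config = config or GDConfig()
    kernel = gaussian_kernel(config.s, config.effective_sigma)
    gds = []
    for im in stack:
        plane = to_single_channel(im)
        pair = directional_differences(plane, boundary=config.boundary)
        dmap = edge_magnitude(pair, rule=config.magnitude_rule)
        gds.append(smooth_differences(dmap, kernel, boundary=config.boundary))
    return normalize_weights(gds)


def gd_fuse(stack: ImageStack, config: GDConfig | None = None) -> FusedImage:
    """Run the full five-step pipeline on a stack."""
    config = config or GDConfig()
    return fuse(stack, compute_weights(stack, config))
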