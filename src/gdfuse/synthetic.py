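"""Seeded synthetic stacks for the four fusion regimes.

Real fusion benchmarks pair co-registered images that each miss part of
the scene's information: CT/MR-style modality pairs showing
complementary structures, infrared/visible pairs with hot objects on a
textureless thermal background, focal-plane pairs blurred in
complementary halves, and exposure brackets clipped at opposite ends.
This module builds such pairs from a seeded ground-truth scene so every
pipeline stage can be exercised — and scored against the truth — with
no external data.

The base scene combines a smooth low-frequency background, a few
geometric shapes, and high-frequency texture patches, so both smooth
and edge-rich regions are present everywhere.  Every generator is
bit-reproducible from (scenario, size, seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .image_io import ImageRaster, ImageStack

__all__ = ["FixtureSpec", "make_base_scene", "make_stack"]

Scenario = Literal["multifocus", "multiexposure", "multimodal", "irvisible"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic stack.

    ``blur_sigma`` controls the out-of-focus defect (multifocus),
    ``exposure_stops`` the +- photographic stops applied before clipping
    (multiexposure), and ``n_shapes`` the structure density.
    """

    scenario: Scenario = "multifocus"
    size: tuple[int, int] = (128, 128)
    seed: int = 0
    K: int = 2
    blur_sigma: float = 3.0
    exposure_stops: float = 1.5
    n_shapes: int = 6

    def __post_init__(self) -> None:
        if self.size[0] < 32 or self.size[1] < 32:
            raise ValueError(f"fixture size must be >= 32x32, got {self.size}")
        if self.scenario not in (
            "multifocus",
            "multiexposure",
            "multimodal",
            "irvisible",
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.K != 2:
            raise ValueError("only two-image stacks are generated")


def _rng(spec: FixtureSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _shapes(
    spec: FixtureSpec, rng: np.random.Generator
) -> list[tuple[np.ndarray, float]]:
    """Random rectangles and disks as (mask, intensity) pairs."""
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w]
    out = []
    for _ in range(spec.n_shapes):
        intensity = float(rng.uniform(0.1, 0.9))
        if rng.random() < 0.5:
            cy, cx = rng.uniform(0.15, 0.85, 2) * (h, w)
            r = rng.uniform(0.05, 0.15) * min(h, w)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        else:
            y0, x0 = rng.uniform(0.1, 0.6, 2) * (h, w)
            dy, dx = rng.uniform(0.1, 0.3, 2) * (h, w)
            mask = (yy >= y0) & (yy < y0 + dy) & (xx >= x0) & (xx < x0 + dx)
        out.append((mask, intensity))
    return out


def make_base_scene(spec: FixtureSpec) -> ImageRaster:
    """The seeded ground-truth scene all degraded views derive from."""
    rng = _rng(spec)
    h, w = spec.size
    background = ndimage.gaussian_filter(rng.normal(size=(h, w)), min(h, w) / 8)
    background = 0.3 + 0.4 * (background - background.min()) / np.ptp(background)
    scene = background
    for mask, intensity in _shapes(spec, rng):
        scene = np.where(mask, 0.6 * intensity + 0.4 * scene, scene)
    texture = ndimage.gaussian_filter(rng.normal(size=(h, w)), 0.8)
    scene = scene + 0.08 * texture
    return ImageRaster(np.clip(scene, 0.0, 1.0))


def _multifocus(
    spec: FixtureSpec, truth: np.ndarray, rng: np.random.Generator
) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    h, w = truth.shape
    blurred = ndimage.gaussian_filter(truth, spec.blur_sigma, mode="nearest")
    left = np.zeros_like(truth, dtype=bool)
    left[:, : w // 2] = True
    # image 1 is blurred on the left (sharp right), image 2 the mirror
    im1 = np.where(left, blurred, truth)
    im2 = np.where(left, truth, blurred)
    masks = {"sharp_1": ~left, "sharp_2": left}
    return [im1, im2], masks


def _multiexposure(
    spec: FixtureSpec, truth: np.ndarray, rng: np.random.Generator
) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    gain = 2.0**spec.exposure_stops
    over = truth * gain
    under = truth / gain
    masks = {"clipped_1": over >= 1.0, "clipped_2": under <= 1.0 / 255}
    return [np.clip(over, 0, 1), np.clip(under, 0, 1)], masks


def _multimodal(
    spec: FixtureSpec, truth: np.ndarray, rng: np.random.Generator
) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    # complementary structure subsets on distinct smooth backgrounds,
    # CT/MR style: each "modality" sees only half of the shapes
    h, w = spec.size
    shape_rng = _rng(spec)
    background = ndimage.gaussian_filter(
        shape_rng.normal(size=(h, w)), min(h, w) / 8
    )  # same draw order as make_base_scene
    shapes = _shapes(spec, shape_rng)
    bg1 = np.full((h, w), 0.25)
    bg2 = np.full((h, w), 0.55)
    im1, im2 = bg1.copy(), bg2.copy()
    vis1 = np.zeros((h, w), dtype=bool)
    vis2 = np.zeros((h, w), dtype=bool)
    for idx, (mask, intensity) in enumerate(shapes):
        if idx % 2 == 0:
            im1 = np.where(mask, intensity, im1)
            vis1 |= mask
        else:
            im2 = np.where(mask, intensity, im2)
            vis2 |= mask
    noise = rng.normal(size=(2, h, w)) * 0.01
    ims = [np.clip(im1 + noise[0], 0, 1), np.clip(im2 + noise[1], 0, 1)]
    return ims, {"structures_1": vis1, "structures_2": vis2}


def _irvisible(
    spec: FixtureSpec, truth: np.ndarray, rng: np.random.Generator
) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    h, w = spec.size
    # IR: bright "hot" blobs on a heavily smoothed, low-texture background
    smooth = ndimage.gaussian_filter(truth, min(h, w) / 16, mode="nearest")
    hot = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(3):
        cy, cx = rng.uniform(0.2, 0.8, 2) * (h, w)
        r = rng.uniform(0.06, 0.12) * min(h, w)
        hot |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    ir = np.where(hot, np.clip(1.2 - smooth, 0, 1), 0.3 * smooth)
    visible = truth
    return [np.clip(ir, 0, 1), visible], {"hot": hot}


_SCENARIOS = {
    "multifocus": _multifocus,
    "multiexposure": _multiexposure,
    "multimodal": _multimodal,
    "irvisible": _irvisible,
}


def make_stack(
    spec: FixtureSpec,
) -> tuple[ImageStack, ImageRaster, dict[str, np.ndarray]]:
    """Build a degraded two-image stack plus ground truth and masks.

    The masks describe where each member is faithful to the truth
    (sharp half, clipped region, visible structures, hot objects),
    enabling reference-based assertions the standard referenceless
    metrics cannot provide.
    """
    truth = make_base_scene(spec)
    rng = _rng(FixtureSpec(**{**spec.__dict__, "seed": spec.seed + 1}))
    planes, masks = _SCENARIOS[spec.scenario](spec, truth.pixels, rng)
    stack = ImageStack(tuple(ImageRaster(p) for p in planes))
    return stack, truth, masks
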