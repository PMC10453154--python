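"""Objective fusion-quality metrics and method ranking.

Nine metrics compare a fused image ``F`` against its source stack:

====== ======================================== ============
name   quantity                                 orientation
====== ======================================== ============
EN     Shannon entropy of F (bits, 256 levels)  higher
MI     sum of mutual informations MI(I_k, F)    higher
PSNR   peak signal-to-noise ratio (dB, L=255)   higher
Qabf   gradient-preservation score (Xydeas-     higher
       Petrovic edge strength/orientation)
SSIM   sum of structural similarities           higher
Qcb    Chen-Blum perceptual score (contrast-    higher
       sensitivity filtering + masking)
CE     mean cross entropy of source vs fused    lower
       histograms (bits)
RMSE   mean root-mean-square error              lower
Qcv    Chen-Varshney region-saliency-weighted   lower
       perceptual distortion
====== ======================================== ============

All metrics are defined on gray-level images; RGB inputs are reduced to
the channel mean first.  Histogram-based metrics quantize the unit range
into 256 uniform levels; PSNR and Qcv operate on the 0..255 gray scale.

Aggregation over the K sources follows the magnitudes that circulate in
the fusion literature: MI and SSIM are *sums* over sources (so a perfect
two-source fusion scores SSIM = 2), while PSNR, CE and RMSE use the
*mean* of the per-source values.  Both modes are selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity

from .image_io import ImageRaster, ImageStack, to_single_channel

__all__ = [
    "HIGHER_BETTER",
    "LOWER_BETTER",
    "METRIC_NAMES",
    "MetricReport",
    "QabfConstants",
    "entropy",
    "mutual_information",
    "psnr",
    "qabf",
    "ssim_fusion",
    "qcb",
    "cross_entropy",
    "rmse",
    "qcv",
    "evaluate_all",
    "rank_methods",
]

HIGHER_BETTER = ("EN", "MI", "PSNR", "Qabf", "SSIM", "Qcb")
LOWER_BETTER = ("CE", "RMSE", "Qcv")
METRIC_NAMES = HIGHER_BETTER + LOWER_BETTER

PSNR_CAP_DB = 100.0
CE_EPS = 1e-12


@dataclass(frozen=True)
class MetricReport:
    """Named metric values plus each metric's orientation."""

    values: dict[str, float]
    orientation: dict[str, str] = field(
        default_factory=lambda: {
            **{m: "higher" for m in HIGHER_BETTER},
            **{m: "lower" for m in LOWER_BETTER},
        }
    )

    def __post_init__(self) -> None:
        missing = set(METRIC_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"report missing metrics: {sorted(missing)}")


# --------------------------------------------------------------------------
# helpers

def _plane(img: ImageRaster) -> np.ndarray:
    return to_single_channel(img).pixels


def _quantize(plane: np.ndarray) -> np.ndarray:
    """Unit-range plane -> integer gray levels 0..255."""
    return np.clip(np.rint(plane * 255.0), 0, 255).astype(np.intp)


def _histogram(plane: np.ndarray) -> np.ndarray:
    h = np.bincount(_quantize(plane).ravel(), minlength=256).astype(np.float64)
    return h / h.sum()


# --------------------------------------------------------------------------
# information-theoretic metrics

def entropy(img: ImageRaster) -> float:
    """Shannon entropy in bits of the 256-level histogram; in [0, 8]."""
    h = _histogram(_plane(img))
    nz = h[h > 0]
    return float(-(nz * np.log2(nz)).sum())


def _pairwise_mi(a: np.ndarray, b: np.ndarray) -> float:
    joint = np.zeros((256, 256))
    qa, qb = _quantize(a).ravel(), _quantize(b).ravel()
    np.add.at(joint, (qa, qb), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())


def mutual_information(
    stack: ImageStack,
    fused: ImageRaster,
    aggregate: Literal["sum", "mean"] = "sum",
) -> float:
    """Total mutual information shared between the sources and F (bits)."""
    f = _plane(fused)
    vals = [_pairwise_mi(_plane(im), f) for im in stack]
    return float(np.sum(vals) if aggregate == "sum" else np.mean(vals))


def cross_entropy(
    stack: ImageStack,
    fused: ImageRaster,
    aggregate: Literal["mean", "sum"] = "mean",
) -> float:
    """Histogram divergence between each source and F, averaged (bits).

    Per pair: ``sum h_I log2(h_I / h_F)`` over bins with ``h_I > 0``;
    empty fused bins are smoothed with a 1e-12 floor so disjoint
    supports stay finite.
    """
    hf = _histogram(_plane(fused))
    hf = np.where(hf == 0, CE_EPS, hf)
    vals = []
    for im in stack:
        hi = _histogram(_plane(im))
        nz = hi > 0
        vals.append(float((hi[nz] * np.log2(hi[nz] / hf[nz])).sum()))
    return float(np.mean(vals) if aggregate == "mean" else np.sum(vals))


# --------------------------------------------------------------------------
# fidelity metrics

def psnr(
    stack: ImageStack,
    fused: ImageRaster,
    aggregate: Literal["mean", "sum"] = "mean",
) -> float:
    """PSNR in dB on the 0..255 scale, capped at 100 dB when MSE -> 0."""
    f = _plane(fused) * 255.0
    mses = [float(np.mean((_plane(im) * 255.0 - f) ** 2)) for im in stack]
    mse = float(np.mean(mses) if aggregate == "mean" else np.sum(mses))
    if mse <= 0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(255.0**2 / mse), PSNR_CAP_DB))


def rmse(
    stack: ImageStack,
    fused: ImageRaster,
    aggregate: Literal["mean", "sum"] = "mean",
) -> float:
    """Mean per-source root-mean-square error on the unit scale."""
    f = _plane(fused)
    vals = [float(np.sqrt(np.mean((_plane(im) - f) ** 2))) for im in stack]
    return float(np.mean(vals) if aggregate == "mean" else np.sum(vals))


def ssim_fusion(
    stack: ImageStack,
    fused: ImageRaster,
    aggregate: Literal["sum", "mean"] = "sum",
) -> float:
    """Structural similarity of F to each source, summed over sources.

    Each term uses the standard 11x11 Gaussian window (sigma 1.5) with
    stabilizers c1 = (0.01 L)^2, c2 = (0.03 L)^2, so a two-source stack
    with F identical to both sources scores exactly 2.
    """
    f = _plane(fused)
    vals = [
        structural_similarity(
            _plane(im),
            f,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
        for im in stack
    ]
    return float(np.sum(vals) if aggregate == "sum" else np.mean(vals))


# --------------------------------------------------------------------------
# Qabf — gradient preservation

@dataclass(frozen=True)
class QabfConstants:
    """Sigmoid constants of the edge-preservation model.

    ``gamma_g, kappa_g, sigma_g`` shape the strength-preservation
    sigmoid; ``gamma_a, kappa_a, sigma_a`` the orientation one.  With
    ``normalize_identity`` (default) the per-pixel score is divided by
    its value at perfect preservation, so an F identical to its sources
    scores exactly 1; with the raw sigmoids the ceiling is ~0.975.
    """

    gamma_g: float = 0.9994
    kappa_g: float = -15.0
    sigma_g: float = 0.5
    gamma_a: float = 0.9879
    kappa_a: float = -22.0
    sigma_a: float = 0.8
    normalize_identity: bool = True


def _sobel_strength_orientation(plane: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Sobel gradient magnitude and angle in (-pi/2, pi/2]."""
    gx = ndimage.sobel(plane, axis=1, mode="nearest")
    gy = ndimage.sobel(plane, axis=0, mode="nearest")
    g = np.hypot(gx, gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.arctan(np.divide(gy, gx, out=np.zeros_like(gy), where=gx != 0))
    alpha = np.where((gx == 0) & (gy != 0), np.pi / 2, alpha)
    return g, alpha


def _preservation(
    g_src: np.ndarray,
    a_src: np.ndarray,
    g_f: np.ndarray,
    a_f: np.ndarray,
    c: QabfConstants,
) -> np.ndarray:
    big = np.maximum(g_src, g_f)
    small = np.minimum(g_src, g_f)
    G = np.where(big > 0, small / np.where(big > 0, big, 1.0), 1.0)
    A = 1.0 - np.abs(a_src - a_f) / (np.pi / 2)
    qg = c.gamma_g / (1.0 + np.exp(c.kappa_g * (G - c.sigma_g)))
    qa = c.gamma_a / (1.0 + np.exp(c.kappa_a * (A - c.sigma_a)))
    q = qg * qa
    if c.normalize_identity:
        q0 = (
            c.gamma_g / (1.0 + np.exp(c.kappa_g * (1.0 - c.sigma_g)))
            * c.gamma_a / (1.0 + np.exp(c.kappa_a * (1.0 - c.sigma_a)))
        )
        q = q / q0
    return q


def qabf(
    a: ImageRaster,
    b: ImageRaster,
    fused: ImageRaster,
    constants: QabfConstants | None = None,
) -> float:
    """Edge-information preservation score in [0, 1].

    Sobel strength and orientation are extracted from each source and
    from F; per-pixel preservation factors are mapped through sigmoids
    and averaged with the source edge strengths as weights.  A stack of
    constant images has zero total weight and scores 0 by convention.
    """
    c = constants or QabfConstants()
    pa, pb, pf = _plane(a), _plane(b), _plane(fused)
    ga, aa = _sobel_strength_orientation(pa)
    gb, ab = _sobel_strength_orientation(pb)
    gf, af = _sobel_strength_orientation(pf)
    q_af = _preservation(ga, aa, gf, af, c)
    q_bf = _preservation(gb, ab, gf, af, c)
    wa, wb = ga, gb
    denom = float((wa + wb).sum())
    if denom == 0:
        return 0.0
    return float((q_af * wa + q_bf * wb).sum() / denom)


# --------------------------------------------------------------------------
# Qcb — Chen-Blum perceptual score

#: Difference-of-Gaussians contrast-sensitivity filter and masking
#: constants of the Chen-Blum model.
QCB_PARAMS = dict(
    f0=15.3870, f1=1.3456, a=0.7622,  # CSF (radial frequency, DoG form)
    k=1.0, h=1.0, p=3.0, q=2.0, Z=0.0001,  # contrast masking
    sigma1=2.0, sigma2=4.0,  # local-contrast Gaussian pair
)


def _radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    """Radial frequency grid in cycles per image, FFT-ordered."""
    m, n = shape
    u = np.fft.fftfreq(n) * n
    v = np.fft.fftfreq(m) * m
    return np.hypot(u[None, :], v[:, None])


def _csf_filter_dog(plane: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
    r = _radial_frequency(plane.shape)
    S = np.exp(-((r / params["f0"]) ** 2)) - params["a"] * np.exp(
        -((r / params["f1"]) ** 2)
    )
    return np.real(np.fft.ifft2(np.fft.fft2(plane) * S))


def _masked_contrast(plane: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
    filt = _csf_filter_dog(plane, params)
    lo1 = ndimage.gaussian_filter(filt, params["sigma1"], mode="nearest")
    lo2 = ndimage.gaussian_filter(filt, params["sigma2"], mode="nearest")
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = np.where(lo2 != 0, lo1 / np.where(lo2 != 0, lo2, 1.0) - 1.0, 0.0)
    c = np.abs(contrast)
    return (params["k"] * c ** params["p"]) / (
        params["h"] * c ** params["q"] + params["Z"]
    )


def qcb(
    a: ImageRaster,
    b: ImageRaster,
    fused: ImageRaster,
    params: Mapping[str, float] | None = None,
) -> float:
    """Chen-Blum referenceless perceptual fusion score (higher better).

    Each image is contrast-sensitivity filtered in the frequency
    domain, converted to a masked local-contrast map, and the fused
    map's contrast preservation relative to each source is weighted by
    source saliency and averaged over the image.  F identical to both
    sources gives preservation 1 everywhere and a score of 1.
    """
    p = dict(QCB_PARAMS)
    if params:
        p.update(params)
    ca = _masked_contrast(_plane(a) * 255.0, p)
    cb_ = _masked_contrast(_plane(b) * 255.0, p)
    cf = _masked_contrast(_plane(fused) * 255.0, p)

    def preserve(cs: np.ndarray) -> np.ndarray:
        big = np.maximum(cs, cf)
        small = np.minimum(cs, cf)
        return np.where(big > 0, small / np.where(big > 0, big, 1.0), 1.0)

    sal = ca**2 + cb_**2
    lam_a = np.where(sal > 0, ca**2 / np.where(sal > 0, sal, 1.0), 0.5)
    lam_b = 1.0 - lam_a
    return float(np.mean(lam_a * preserve(ca) + lam_b * preserve(cb_)))


# --------------------------------------------------------------------------
# Qcv — Chen-Varshney region-weighted distortion

QCV_WINDOW = 16


def _csf_filter_mannos(plane: np.ndarray) -> np.ndarray:
    """Mannos-Sakrison band-pass CSF applied in the frequency domain."""
    r = _radial_frequency(plane.shape)
    S = 2.6 * (0.0192 + 0.114 * r) * np.exp(-((0.114 * r) ** 1.1))
    return np.real(np.fft.ifft2(np.fft.fft2(plane) * S))


def qcv(
    stack: ImageStack,
    fused: ImageRaster,
    window: int = QCV_WINDOW,
) -> float:
    """Chen-Varshney perceptual distortion (lower better).

    The image is tiled into ``window``-sized regions (the trailing
    remainder is dropped).  Each source contributes, per region, a
    saliency (its local Sobel edge energy) and a distortion (the mean
    squared CSF-filtered difference to F on the 0..255 scale); the
    score is the saliency-weighted mean distortion, invariant to any
    common rescaling of the saliencies.
    """
    f = _plane(fused) * 255.0
    h, w = f.shape
    nh, nw = h // window, w // window
    if nh == 0 or nw == 0:
        raise ValueError(f"image smaller than one {window}x{window} region")

    def per_region(arr: np.ndarray) -> np.ndarray:
        trimmed = arr[: nh * window, : nw * window]
        return trimmed.reshape(nh, window, nw, window).sum(axis=(1, 3))

    num = 0.0
    den = 0.0
    for im in stack:
        x = _plane(im) * 255.0
        gx = ndimage.sobel(x, axis=1, mode="nearest")
        gy = ndimage.sobel(x, axis=0, mode="nearest")
        lam = per_region(gx**2 + gy**2)
        dfilt = _csf_filter_mannos(x - f)
        dist = per_region(dfilt**2) / window**2
        num += float((lam * dist).sum())
        den += float(lam.sum())
    if den == 0:
        return 0.0
    return num / den


# --------------------------------------------------------------------------
# bundle + ranking

def evaluate_all(stack: ImageStack, fused: ImageRaster) -> MetricReport:
    """All nine metrics for one fused image.

    Qabf and Qcb are defined pairwise; for K > 2 they (and Qcv's
    two-source convention) are computed over the first two sources with
    a warning — the literature does not define a K > 2 extension.
    """
    if stack.K > 2:
        warnings.warn(
            "Qabf/Qcb computed over the first two sources only", stacklevel=2
        )
    values = {
        "EN": entropy(fused),
        "MI": mutual_information(stack, fused),
        "PSNR": psnr(stack, fused),
        "Qabf": qabf(stack[0], stack[1], fused),
        "SSIM": ssim_fusion(stack, fused),
        "Qcb": qcb(stack[0], stack[1], fused),
        "CE": cross_entropy(stack, fused),
        "RMSE": rmse(stack, fused),
        "Qcv": qcv(stack, fused),
    }
    return MetricReport(values=values)


def rank_methods(
    table: pd.DataFrame,
    orientations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Average-rank aggregation of a methods x metrics score table.

    Per metric, rank 1 is best (respecting the metric's orientation);
    ties receive averaged ranks.  The returned frame has one rank column
    per metric plus an ``average_rank`` column; with n methods every
    metric's ranks are a tie-averaged permutation of 1..n.
    """
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise ValueError("score table contains non-finite values")
    if orientations is None:
        orientations = {
            **{m: "higher" for m in HIGHER_BETTER},
            **{m: "lower" for m in LOWER_BETTER},
        }
    ranks = {}
    for col in table.columns:
        orient = orientations.get(col, "higher")
        ranks[col] = table[col].rank(
            ascending=(orient == "lower"), method="average"
        )
    out = pd.DataFrame(ranks, index=table.index)
    out["average_rank"] = out.mean(axis=1)
    return out
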