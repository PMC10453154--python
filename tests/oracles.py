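"""Independent brute-force oracles.

Straight-line, nested-loop implementations of the fusion pipeline and
the heavier perceptual metrics, deliberately kept separate from the
package's vectorized code paths.  Only usable at small sizes.
"""

from __future__ import annotations

import math

import numpy as np


def naive_gd_fuse(planes, s, sigma, rule="euclidean"):
    """Per-pixel loop version of the five fusion steps (replicate boundary).

    ``planes`` is a list of K 2-D arrays; returns the fused plane.
    """
    K = len(planes)
    H, W = planes[0].shape

    def at(img, i, j):  # replicate boundary
        return img[min(max(i, 0), H - 1), min(max(j, 0), W - 1)]

    # step 1-2: differences and magnitude
    dmaps = []
    for img in planes:
        d = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                cd = img[i, j] - at(img, i, j + 1)
                rd = img[i, j] - at(img, i + 1, j)
                if rule == "euclidean":
                    d[i, j] = math.sqrt(cd * cd + rd * rd)
                elif rule == "sum_abs":
                    d[i, j] = abs(cd) + abs(rd)
                elif rule == "sum_sq":
                    d[i, j] = cd * cd + rd * rd
                else:
                    raise ValueError(rule)
        dmaps.append(d)

    # step 3: Gaussian window, normalized
    side = 2 * s + 1
    w = np.zeros((side, side))
    for p in range(-s, s + 1):
        for r in range(-s, s + 1):
            w[p + s, r + s] = math.exp(-(p * p + r * r) / (2.0 * sigma * sigma))
    w /= w.sum()
    gds = []
    for d in dmaps:
        gd = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for p in range(-s, s + 1):
                    for r in range(-s, s + 1):
                        acc += w[p + s, r + s] * at(d, i + p, j + r)
                gd[i, j] = acc
        gds.append(gd)

    # step 4-5: normalize and blend
    fused = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            total = sum(gd[i, j] for gd in gds)
            for k in range(K):
                fw = (1.0 / K) if total < 1e-12 else gds[k][i, j] / total
                fused[i, j] += fw * planes[k][i, j]
    return np.clip(fused, 0.0, 1.0)


SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T


def _sobel_loops(plane):
    """Sobel strength + orientation by explicit loops, replicate boundary."""
    H, W = plane.shape
    g = np.zeros((H, W))
    alpha = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            sx = sy = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    v = plane[min(max(i + di, 0), H - 1), min(max(j + dj, 0), W - 1)]
                    sx += SOBEL_X[di + 1, dj + 1] * v
                    sy += SOBEL_Y[di + 1, dj + 1] * v
            g[i, j] = math.hypot(sx, sy)
            if sx == 0:
                alpha[i, j] = math.pi / 2 if sy != 0 else 0.0
            else:
                alpha[i, j] = math.atan(sy / sx)
    return g, alpha


def naive_qabf(a, b, f, gamma_g=0.9994, kappa_g=-15.0, sigma_g=0.5,
               gamma_a=0.9879, kappa_a=-22.0, sigma_a=0.8,
               normalize_identity=True):
    """Per-pixel transcription of the gradient-preservation score."""
    ga, aa = _sobel_loops(a)
    gb, ab = _sobel_loops(b)
    gf, af = _sobel_loops(f)
    q0 = (gamma_g / (1 + math.exp(kappa_g * (1 - sigma_g)))
          * gamma_a / (1 + math.exp(kappa_a * (1 - sigma_a))))
    H, W = a.shape
    num = den = 0.0
    for i in range(H):
        for j in range(W):
            for gs, als, w in ((ga[i, j], aa[i, j], ga[i, j]),
                               (gb[i, j], ab[i, j], gb[i, j])):
                hi, lo = max(gs, gf[i, j]), min(gs, gf[i, j])
                G = lo / hi if hi > 0 else 1.0
                A = 1.0 - abs(als - af[i, j]) / (math.pi / 2)
                qg = gamma_g / (1 + math.exp(kappa_g * (G - sigma_g)))
                qa = gamma_a / (1 + math.exp(kappa_a * (A - sigma_a)))
                q = qg * qa
                if normalize_identity:
                    q /= q0
                num += q * w
                den += w
    return 0.0 if den == 0 else num / den


def _fft_filter(plane, response):
    return np.real(np.fft.ifft2(np.fft.fft2(plane) * response))


def _radial(shape):
    m, n = shape
    u = np.fft.fftfreq(n) * n
    v = np.fft.fftfreq(m) * m
    r = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            r[i, j] = math.hypot(u[j], v[i])
    return r


def _gauss_blur_loops(plane, sigma):
    """Truncated (4 sigma) Gaussian blur by loops, replicate boundary."""
    H, W = plane.shape
    s = int(4 * sigma + 0.5)
    w = np.zeros((2 * s + 1, 2 * s + 1))
    for p in range(-s, s + 1):
        for r in range(-s, s + 1):
            w[p + s, r + s] = math.exp(-(p * p + r * r) / (2 * sigma * sigma))
    w /= w.sum()
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for p in range(-s, s + 1):
                for r in range(-s, s + 1):
                    acc += w[p + s, r + s] * plane[
                        min(max(i + p, 0), H - 1), min(max(j + r, 0), W - 1)
                    ]
            out[i, j] = acc
    return out


def naive_qcb(a, b, f, f0=15.3870, f1=1.3456, aa=0.7622,
              k=1.0, h=1.0, p=3.0, q=2.0, Z=0.0001,
              sigma1=2.0, sigma2=4.0):
    """Transcription of the perceptual contrast-preservation score."""
    r = _radial(a.shape)
    S = np.exp(-((r / f0) ** 2)) - aa * np.exp(-((r / f1) ** 2))

    def masked_contrast(plane):
        filt = _fft_filter(plane * 255.0, S)
        lo1 = _gauss_blur_loops(filt, sigma1)
        lo2 = _gauss_blur_loops(filt, sigma2)
        H, W = plane.shape
        out = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                c = abs(lo1[i, j] / lo2[i, j] - 1.0) if lo2[i, j] != 0 else 0.0
                out[i, j] = k * c**p / (h * c**q + Z)
        return out

    ca, cb, cf = masked_contrast(a), masked_contrast(b), masked_contrast(f)
    H, W = a.shape
    total = 0.0
    for i in range(H):
        for j in range(W):
            sal = ca[i, j] ** 2 + cb[i, j] ** 2
            lam_a = ca[i, j] ** 2 / sal if sal > 0 else 0.5
            lam_b = 1.0 - lam_a

            def preserve(cs):
                hi, lo = max(cs, cf[i, j]), min(cs, cf[i, j])
                return lo / hi if hi > 0 else 1.0

            total += lam_a * preserve(ca[i, j]) + lam_b * preserve(cb[i, j])
    return total / (H * W)


def naive_qcv(planes, f, window=16):
    """Transcription of the saliency-weighted perceptual distortion."""
    r = _radial(f.shape)
    S = 2.6 * (0.0192 + 0.114 * r) * np.exp(-((0.114 * r) ** 1.1))
    H, W = f.shape
    nh, nw = H // window, W // window
    num = den = 0.0
    for x in planes:
        x255, f255 = x * 255.0, f * 255.0
        gx_gy_sq = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                sx = sy = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        v = x255[min(max(i + di, 0), H - 1),
                                 min(max(j + dj, 0), W - 1)]
                        sx += SOBEL_X[di + 1, dj + 1] * v
                        sy += SOBEL_Y[di + 1, dj + 1] * v
                gx_gy_sq[i, j] = sx * sx + sy * sy
        dfilt = _fft_filter(x255 - f255, S)
        for bi in range(nh):
            for bj in range(nw):
                sl = (slice(bi * window, (bi + 1) * window),
                      slice(bj * window, (bj + 1) * window))
                lam = gx_gy_sq[sl].sum()
                dist = (dfilt[sl] ** 2).sum() / window**2
                num += lam * dist
                den += lam
    return 0.0 if den == 0 else num / den
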