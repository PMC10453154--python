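# Methods

## Fusion model

`gdfuse` fuses K ≥ 2 co-registered images by a per-pixel convex
combination whose weights are each image's *edge activity*: the
first-order gradient magnitude, smoothed with an isotropic Gaussian
window so that a pixel's weight reflects the information content of its
neighborhood, not just itself. The model assumes the sources are
spatially registered and radiometrically comparable after scaling to
the unit range; it performs no alignment, denoising or tone mapping.
Because the weights are a ratio of identically filtered activities, the
output is invariant to any common positive rescaling of the kernel, and
permuting the input order permutes the weight maps without changing the
fused image.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `s` | Gaussian half-size (window side `2s+1`, pixels) | 10 | presets 5 / 10 / 15 |
| `sigma` | Gaussian spread (pixels) | `"auto"` = `s/3` | presets store 1.6 / 3.3 / 5 |
| `magnitude_rule` | combination of the two directional differences | `euclidean` | also `sum_abs`, `sum_sq` |
| `boundary` | treatment of missing neighbors | `replicate` | also `zero` |

Larger `s` pools activity over a wider neighborhood, which produces
smoother weight maps and, on the synthetic benchmarks here, usually
better scores at the cost of softer weight transitions.

### Numerical choices

- **Directional-difference ambiguity.** The two difference maps can be
  combined as a Euclidean gradient magnitude, an absolute sum, or a sum
  of squares; the three are monotone-related but yield different weight
  ratios. The Euclidean magnitude is the default (it is the stated
  intent of the construction); the alternatives stay selectable rather
  than hard-coded because the weights, being ratios, are genuinely
  sensitive to the choice.
- **Boundary handling** is edge replication for both the differences
  (the last row/column difference is 0) and the convolution.
  Zero-padding would manufacture spurious high activity along borders
  and systematically bias border weights; replication is the neutral
  choice and `zero` is kept for comparison.
- **Flat regions.** Where the summed activity falls below 1e−12 the
  ratio is undefined; those pixels get uniform `1/K` weights — flat
  everywhere in every source means no source has a claim, and uniform
  averaging is the information-free fallback.
- **RGB inputs.** Activity is measured on the unweighted channel mean
  and a single weight map per image is applied to all three channels.
  Per-channel weights could disagree at an edge and produce color
  fringing; a shared map cannot. The plain mean (not luma weights) keeps
  the reduction symmetric; it is a config-level choice, not a constant.
- The kernel is normalized to unit sum. This is provably irrelevant to
  the fused image (the ratio cancels any scale — tested explicitly) but
  keeps the smoothed activity on the scale of the raw magnitudes.

## Pattern-search tuning (GDPS)

A classic compass search maximizes a chosen quality metric over
`(s, sigma)` in the box `[5, 80] × [1, 100]` from the start `(10, 3.3)`
with at most 20 polls: the four axis neighbors at the current mesh size
are polled in the fixed order `+s, −s, +sigma, −sigma` with
first-improvement acceptance; the mesh doubles on success and halves on
failure (initial mesh 1, tolerance 1e−3 — textbook compass-search
constants; the published setup fixes only the box, start, iteration
count and the "classic" algorithm variant). Candidates are clamped to
the box, so every iterate is feasible; the incumbent is returned, so
the final objective never falls below its starting value; the
evaluation count is bounded by `1 + 4·max_iter`. `s` is searched as a
real and rounded to the nearest integer (floored at 1) only when the
kernel is built — the box says nothing about integrality, and keeping
the space continuous is what a generic pattern search expects.
Objectives are normalized to maximization internally (Qcv, a
distortion, is negated). The search is deterministic: identical inputs
give identical traces.

A caveat that matters for interpretation: because `s` is rounded,
polls at mesh sizes < 0.5 along `s` re-evaluate the same integer
kernel, so late iterations mostly refine `sigma`.

## Quality metrics

EN, MI and CE quantize intensities to 256 uniform levels over the unit
range (matching the 255-level gray scale the decibel and histogram
formulas assume); PSNR and Qcv operate on the 0–255 scale; RMSE on the
unit scale. Metrics defined on gray-level images receive the channel
mean of RGB inputs.

- **Aggregation over sources** (not standardized in the literature):
  MI and SSIM are *sums* over the K sources — reported fusion SSIM
  values above 1 are only consistent with summation — while PSNR, CE
  and RMSE are *means*. Both modes are exposed as an argument.
- **EN** is standard Shannon entropy in bits (base 2, negated sum);
  only bits put 8-bit images in the expected 0–8 range.
- **PSNR** is capped at 100 dB when the MSE vanishes: a finite,
  sortable sentinel so ranking tables never see infinities.
- **CE** smooths empty fused-histogram bins with 1e−12 (applied to the
  fused side only) so disjoint supports stay finite.
- **Qabf** uses Sobel strength/orientation and the published sigmoid
  constants (Γ_g = 0.9994, κ_g = −15, σ_g = 0.5; Γ_α = 0.9879,
  κ_α = −22, σ_α = 0.8), kept in a config object. With the raw
  sigmoids, *perfect* preservation scores ≈ 0.975, not 1 — the
  sigmoids do not saturate at unit ratio. The per-pixel score is
  therefore normalized by its value at perfect preservation
  (`normalize_identity=True`, a global rescale by ≈ 1.026) so the
  identity limit is exactly 1; the raw convention remains selectable.
  An all-constant triple has zero total edge weight and scores 0 by
  convention.
- **SSIM** terms use the standard 11×11 Gaussian window (σ = 1.5),
  c1 = (0.01·255)², c2 = (0.03·255)² via scikit-image.
- **Qcb** filters each image with a difference-of-Gaussians
  contrast-sensitivity function in the frequency domain
  (f0 = 15.387, f1 = 1.3456, a = 0.7622 on a cycles-per-image radial
  grid), forms local contrast from a σ = 2 / σ = 4 Gaussian pair,
  applies contrast masking (k = h = 1, p = 3, q = 2, Z = 1e−4), and
  averages min/max contrast-preservation ratios weighted by squared-
  contrast saliency. Pixels where both saliencies vanish split 50/50
  and count as preserved.
- **Qcv** tiles the image into 16×16 regions (trailing remainder
  dropped), weighs each region by its Sobel edge energy, and measures
  distortion as the region-mean squared Mannos–Sakrison-filtered
  difference between source and fused image; the score is the
  saliency-weighted mean, invariant to a common rescaling of the
  saliencies.
- **Ranking** uses tie-averaged ranks per metric (1 = best respecting
  orientation) and averages across metrics.

Qabf, Qcb and Qcv are defined pairwise; for K > 2 they are computed
over the first two sources with a warning. This is a placeholder, not
an interpretation — no accepted K > 2 extension exists.

## Synthetic benchmarks

The generator builds a seeded ground-truth scene — a low-frequency
Gaussian-blurred-noise background in [0.3, 0.7], six random
rectangles/disks, and fine (σ = 0.8) texture — then derives degraded
pairs per scenario:

- **multifocus**: Gaussian blur (σ = 3) on complementary halves; each
  member equals the truth exactly on its sharp half, and masks record
  where.
- **multiexposure**: gain ±1.5 photographic stops with hard clipping;
  the over-exposed member clips well over 5 % of pixels.
- **multimodal**: the scene's shapes split into two complementary
  subsets drawn on different flat backgrounds (0.25 / 0.55) with mild
  sensor noise — a CT/MR-style complementary-structure pair.
- **irvisible**: a heavily smoothed, contrast-reduced background with
  bright "hot" blobs versus the fully textured truth.

Default size is 128×128: large enough for the `s = 15` kernel, small
enough for sub-second tests. The optimizer tests and study use 64×64
to keep the ≤ 81-evaluation search fast. Ground truth is retained so
reference-based checks (RMSE against truth) are possible even though
the standard metric suite is referenceless or input-referenced.

What these fixtures do **not** emulate: registration error, sensor
noise statistics, nonlinear camera response, realistic IR radiometry,
or natural-image texture spectra. Passing the efficacy tests shows the
weighting mechanism selects the informative source under clean,
idealized degradations; it does not certify performance on real
clinical or surveillance imagery.

## Verification strategy

Every pipeline stage has closed-form or hand-evaluated cases, and the
full five-step pipeline is checked against an independent nested-loop
implementation (16×16, s ≤ 3, K ≤ 3, agreement 1e−12). Qabf, Qcb and
Qcv are each checked against separate straight-line transcriptions of
their defining formulas (1e−10 on ≤ 32×32 fixtures). Structural
invariants — weight conservation, convexity, permutation equivariance,
kernel-scale invariance, optimizer monotonicity/feasibility/budget —
are asserted as property tests over seeded inputs.

## Known limitations

- Histogram-based MI is strongly positively biased on small images
  (256² joint bins); MI values from small fixtures are comparable with
  each other, not with large-image MI.
- The weight maps are smooth, not binary: in multi-focus fusion a thin
  transition band around the focus boundary blends sharp and blurred
  content instead of selecting.
- Pairwise-only Qabf/Qcb/Qcv restrict GDPS objectives to the first two
  sources of a K > 2 stack.
- Very large kernels relative to the image (side > image extent) are
  accepted with a warning but make the weights nearly global.
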