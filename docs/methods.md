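# Methods

## Scope and model

`mammoprep` preprocesses 2-D grayscale mammograms in a fixed, configurable
three-stage chain — artifact-adaptive median filtering, z-score
normalization, energy-curve contrast enhancement — and provides the
surrounding machinery a study needs: geometric standardization, synthetic
phantoms, leakage-safe cohort splitting, and segmentation/classification
evaluation with bootstrap uncertainty. No learning component is included;
the package stops where model training begins.

Images are integer grids over `[0, R−1]` with R = 256 (8-bit) or 65536
(16-bit); coordinates are 0-based (row, column). All internal math uses
this convention.

## Adaptive median filter

Bright artifacts ("light spots") are detected by thresholding at
mean + k·σ (k = 2.5), labeling 8-connected components and keeping those of
at least 16 px. These three parameters are exposed because artifact
detection is acquisition-dependent; the defaults suit label tags and
opacities that sit far above tissue intensities.

Each spot contributes a center (rounded centroid), bounding-box extents
(he, wi), and an effective radius a = min(he, wi)/2. A pixel's window size
depends on the Euclidean distance *sdis* to the nearest spot center:
exponentially growing inside the radius (U = 2(e^{a/sdis} − 1) + 3, with
sdis = 0 mapped to the cap, the limit of that branch), logarithmically
outside (U = 2·log₁₀(sdis/a) + 3). Values are floored to odd integers and
clamped to [u_min, S_dis] with u_min = 3 — smaller windows do not remove
impulse corruption reliably — and S_dis = floor(min spot dimension / 4)
(odd), so the window never dwarfs the artifact; with no spots the cap
defaults to 9 and the whole image uses the 3×3 floor.

Numerical choices: windows are clipped at image borders rather than padded
(no pixel values are invented), and even-count windows use the lower
median, so every output intensity is attained in its input window. The
implementation groups pixels by window size and evaluates each group with a
NaN-padded sliding view; tests verify bit-equality against a naive
per-pixel oracle.

The spot geometry is deliberately simple — a center plus an effective
radius. The radius test (sdis < a) decides the inside/outside branch, which
keeps the two window laws consistent at the boundary; a bounding-box
membership test would not.

## Z-score normalization and re-quantization

The z-score uses the population (1/N) standard deviation. A zero-variance
image yields all zeros with a degenerate flag instead of an error so batch
runs survive blank frames. Because contrast enhancement operates on
discrete levels, the real-valued z-scores are re-quantized by a min–max
affine map onto [0, R−1] with round-half-up; the map is invariant to
positive affine transforms of its input, so the z-score's scale convention
cannot influence the enhancement stage. R = 256 is the default working
depth after normalization.

## Energy-curve contrast enhancement

For level l, b_l(p) = +1 if pix(p) > l else −1, and

E(l) = − Σ_p Σ_{q∈N_p^d} w(p,q)·b_l(p)·b_l(q) + Σ_p Σ_{q∈N_p^d} w(p,q),

with N_p^d the Chebyshev-≤d neighborhood (p excluded, border-clipped) and
w = (1/chebyshev)^f. E(l) is twice the weighted count of neighbor pairs
whose intensities straddle l: zero iff the thresholded field is constant,
and always zero at l = R−1. The implementation computes all levels at once
from two cumulative histograms per neighbor offset (pairs straddling l are
those with min ≤ l < max), which is exact and O(offsets·(N + R)); the test
suite checks it against the direct per-level double sum. The weight
exponent f (range [1, 3], default 1) sharpens the locality of the
neighborhood's influence; with d = 1, f = 1 all weights are 1.

Enhancement then follows clipped, partitioned equalization with the energy
curve in the histogram's role:

1. **Clip** at C = mean + median of the curve, bounding the enhancement
   rate. An all-zero curve (constant image) short-circuits: the image is
   returned unchanged, flagged.
2. **Partition** [0, R−1] into three bands at lo_low = round(l_min + StD)
   and lo_high = round(l_max − StD), where l_min/l_max are the extreme
   levels present and StD is the energy-weighted intensity spread of the
   clipped curve (weighted mean m = Σ l·E_cl(l)/ΣE_cl). When the
   thresholds cross or leave (0, R−1), the partition falls back to
   energy-mass terciles of the clipped curve; if those are degenerate too
   (all mass at one level), fixed thirds of the level range are used. The
   fallback is recorded in the processing report.
3. **Distribute**: per-band pdf = clipped energy normalized by the band's
   mass; cdf = within-band cumulative sum. Zero-mass bands get a uniform
   pdf and a flag.
4. **Transfer**: band [a, b] maps to TrF(l) = a + round((b−a)·cdf(l)) — a
   range-preserving construction in which each band occupies its own output
   interval, the full function is the union of disjoint supports, and
   monotonicity within bands (hence rank preservation) holds by
   construction. Outputs are clamped to [0, R−1].

## Pipeline

Default stage order is filter → normalize → enhance, reorderable in the
config. Each image is processed independently: a failure is recorded in its
report row and the run continues, exiting nonzero only at the end. The
report has exactly one row per manifest row and records spot counts,
window-size statistics, degenerate-stage flags and band boundaries. Configs
serialize to JSON and round-trip exactly, and identical manifest + config +
seed runs are bit-identical.

Geometric standardization pads to square with level 0 (bottom/right —
mammogram background is black) and rescales bilinearly to 1024×1024 by
default (256 in tests and examples for speed), rounding back to integer
levels. Bilinear interpolation is a package choice; nearest-neighbor would
preserve intensities exactly but aliases edges, and higher orders overshoot.

## Synthetic phantoms

A phantom is low-pass-filtered seeded Gaussian noise scaled into the
25–55% intensity band (smoothness σ = 12 px), an optional elliptical lesion
(default semi-axes 20×14 px, +25% of full scale; its exact pixel set is the
ground-truth mask), and bright artifact spots (2 by default, 16–40 px,
rectangles or ellipses at 97% of full scale). Noise models: additive
Gaussian (σ as a fraction of R), multiplicative speckle, 50/50
salt-and-pepper at a given rate, Poisson "quantum" photon noise (the
standard radiographic meaning; 200 expected photons at full scale by
default), and uniform-value impulse noise. Perturbation scenarios add
Gaussian noise at σ = 0.05R/0.10R, scale deviations from the mean by 0.85
(contrast reduction), or block-mean downsample by 2 and re-expand.

Cohorts mix 60% benign / 40% malignant cases by default, two views (CC,
MLO) per case; benign cases carry no lesion so classification ground truth
is unambiguous. Default phantom side is 256 px, which keeps the full chain
well under a second per image.

What the phantoms do **not** emulate: anatomical structure (pectoral
muscle, ducts, skin line), breast-density variation, scanner-specific noise
spectra, or compression artifacts. Passing tests therefore demonstrate the
algorithms' contracts — window laws, median correctness, monotone
transfers, exact splits — not clinical performance on real mammograms.

## Splitting and evaluation

The unit of assignment is the case id; within each label stratum case ids
are shuffled with the seed and cut at largest-remainder boundaries, making
split sizes exact to ±1 per stratum (750/120/130 exactly at n = 1000 with
75/12/13). Strata smaller than 3 cases are rejected rather than silently
merged. The auditor accepts case-level or per-image assignments and
reports, in order of specificity: views of one breast split apart,
lateralities of one case split apart, and any other multi-split case.

Dice and IoU are related by Dice = 2·IoU/(1 + IoU); both score 1 on two
empty masks (agreement on absence, flagged via `masks_both_empty`) so
lesion-free cases remain scoreable. Per-image scores are averaged
unweighted across a case's views before any population statistic. The
bootstrap is the percentile method (no bias correction — the plain
non-parametric variant), resampling cases with replacement, statistic =
mean, 1,000 resamples, linear-interpolation quantiles; mean/SD/median
describe the original scores (SD with n−1). The paired t-test is the
classic closed form with n−1 degrees of freedom; identical inputs give
t = 0, p = 1, while constant nonzero differences raise (the statistic is
undefined). Probabilistic predictions threshold at 0.5; `threshold_sweep`
provides operating-curve exploration without attaching any reference
numbers to it.

## Known limitations

- Spot detection assumes artifacts are the brightest structures; very dense
  tissue near saturation can be misdetected (tune `k_sigma`).
- The energy-curve bands depend on global statistics; localized contrast
  defects are out of reach (no block-wise variant).
- DICOM support is single-frame MONOCHROME2 read-only.
- The evaluation module scores masks and labels; it does not produce them —
  no segmentation or classification model ships with the package.
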