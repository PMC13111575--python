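"""Context-aware contrast enhancement driven by the spatial energy curve.

The energy curve is a spatially aware alternative to the histogram.  For
each gray level ``l`` the image is thresholded into a +/-1 field
``b_l(p) = +1 if pix(p) > l else -1``; the energy

    E(l) = - sum_p sum_{q in N_p^d} w(p,q) b_l(p) b_l(q)
           + sum_p sum_{q in N_p^d} w(p,q)

is the (weighted) count of disagreeing neighbor pairs, doubled: it is zero
when the thresholded field is constant and large when level ``l`` cuts
through busy image structure.  ``N_p^d`` is the Chebyshev-distance-<=d
neighborhood of p (border-clipped, p excluded) and
``w(p,q) = (1 / chebyshev(p,q))^f`` with exponent ``f`` in [1, 3].

Enhancement then mirrors clipped, partitioned histogram equalization with
the energy curve in the histogram's role: the curve is clipped at
mean + median to bound the enhancement rate, split into three bands by an
energy-weighted intensity spread, and each band's cumulative distribution
becomes a monotone transfer function mapping the band onto its own output
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GrayImage

__all__ = [
    "EnergyCurve", "ClippedCurve", "BandPartition", "TransferFunction",
    "compute_energy_curve", "clip_energy_curve", "partition_bands",
    "band_distributions", "build_transfer_function", "enhance_contrast",
]


@dataclass
class EnergyCurve:
    """Per-gray-level energy E(l), l = 0..R-1; E(R-1) is always 0."""

    values: np.ndarray
    neighborhood_d: int = 1
    exponent_f: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("energy curve must be a 1-D vector")
        if (self.values < 0).any():
            raise ValueError("energy values must be non-negative")

    @property
    def R(self) -> int:
        return self.values.shape[0]


@dataclass
class ClippedCurve:
    values: np.ndarray
    clip_threshold: float
    degenerate: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def R(self) -> int:
        return self.values.shape[0]


@dataclass
class BandPartition:
    """Tri-band split of [0, R-1]: [0, lo_low], (lo_low, lo_high], (lo_high, R-1]."""

    lo_low: int
    lo_high: int
    R: int
    std_w: float = 0.0
    l_min: int = 0
    l_max: int = 0
    fallback: bool = False

    def __post_init__(self):
        if not (0 <= self.lo_low < self.lo_high <= self.R - 1):
            raise ValueError(
                f"invalid band thresholds lo_low={self.lo_low}, "
                f"lo_high={self.lo_high} for R={self.R}"
            )

    def band_ranges(self) -> list[tuple[int, int]]:
        return [(0, self.lo_low),
                (self.lo_low + 1, self.lo_high),
                (self.lo_high + 1, self.R - 1)]

    def band_of(self, level: int) -> int:
        if level <= self.lo_low:
            return 0
        if level <= self.lo_high:
            return 1
        return 2


@dataclass
class TransferFunction:
    """Level remapping, monotone within each band, clamped to [0, R-1]."""

    mapping: np.ndarray
    bands: BandPartition

    def __post_init__(self):
        self.mapping = np.asarray(self.mapping, dtype=np.int64)

    def __call__(self, img: GrayImage) -> GrayImage:
        return GrayImage(self.mapping[img.pixels], img.levels)


def _neighbor_offsets(d: int, f: float) -> list[tuple[int, int, float]]:
    offs = []
    for dy in range(-d, d + 1):
        for dx in range(-d, d + 1):
            if dy == 0 and dx == 0:
                continue
            cheb = max(abs(dy), abs(dx))
            offs.append((dy, dx, (1.0 / cheb) ** f))
    return offs


def compute_energy_curve(img: GrayImage, d: int = 1, f: float = 1.0) -> EnergyCurve:
    """Compute E(l) for all levels at once.

    Uses the identity E(l) = 2 * sum_offsets w * #{pairs with
    min(pix_p, pix_q) <= l < max(pix_p, pix_q)}: a disagreeing pair at level
    l is exactly one whose two intensities straddle l.  Two cumulative
    histograms per offset therefore give the whole curve in O(offsets *
    (N + R)) — exactly equal to the per-level double sum.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if not (1.0 <= f <= 3.0):
        raise ValueError(f"f must lie in [1, 3], got {f}")
    pix = img.pixels
    R = img.levels
    z, m = pix.shape
    energy = np.zeros(R, dtype=np.float64)
    for dy, dx, w in _neighbor_offsets(d, f):
        # overlap region of the image with itself shifted by (dy, dx)
        ys = slice(max(0, -dy), min(z, z - dy))
        xs = slice(max(0, -dx), min(m, m - dx))
        a = pix[ys, xs]
        b = pix[max(0, dy):min(z, z + dy), max(0, dx):min(m, m + dx)]
        lo = np.minimum(a, b).ravel()
        hi = np.maximum(a, b).ravel()
        cum_lo = np.cumsum(np.bincount(lo, minlength=R))
        cum_hi = np.cumsum(np.bincount(hi, minlength=R))
        # pairs straddling level l: min <= l < max
        energy += 2.0 * w * (cum_lo - cum_hi)
    return EnergyCurve(energy, neighborhood_d=d, exponent_f=f)


def clip_energy_curve(curve: EnergyCurve) -> ClippedCurve:
    """Clip the curve at mean + median to bound the enhancement rate."""
    v = curve.values
    if not v.any():
        return ClippedCurve(v.copy(), clip_threshold=0.0, degenerate=True)
    c_clip = float(v.mean() + np.median(v))
    return ClippedCurve(np.minimum(v, c_clip), clip_threshold=c_clip)


def _tercile_thresholds(values: np.ndarray) -> tuple[int, int]:
    """Smallest levels at which cumulative energy crosses 1/3 and 2/3."""
    total = values.sum()
    cum = np.cumsum(values)
    lo = int(np.searchsorted(cum, total / 3.0))
    hi = int(np.searchsorted(cum, 2.0 * total / 3.0))
    return lo, hi


def partition_bands(clipped: ClippedCurve, img: GrayImage) -> BandPartition:
    """Split [0, R-1] into three bands around the energy-weighted spread.

    The weighted mean level m and spread StD of the clipped curve give
    lo_low = round(l_min + StD), lo_high = round(l_max - StD), where
    l_min/l_max are the extreme levels present in the image.  When these are
    inconsistent (crossed, or outside the open interval (0, R-1)) the bands
    fall back to energy-mass terciles of the clipped curve; a fully
    degenerate curve falls back to fixed thirds of the level range.
    """
    R = clipped.R
    v = clipped.values
    l_min = int(img.pixels.min())
    l_max = int(img.pixels.max())
    fallback = False
    std_w = 0.0
    if clipped.degenerate or v.sum() == 0:
        lo_low, lo_high = _fixed_thirds(R)
        fallback = True
    else:
        levels = np.arange(R, dtype=np.float64)
        total = v.sum()
        m = float((levels * v).sum() / total)
        std_w = float(np.sqrt(((levels - m) ** 2 * v).sum() / total))
        lo_low = int(np.floor(l_min + std_w + 0.5))
        lo_high = int(np.floor(l_max - std_w + 0.5))
        if not (0 < lo_low < lo_high < R - 1):
            lo_low, lo_high = _tercile_thresholds(v)
            fallback = True
            if not (0 <= lo_low < lo_high <= R - 1):
                lo_low, lo_high = _fixed_thirds(R)
    return BandPartition(lo_low=lo_low, lo_high=lo_high, R=R, std_w=std_w,
                         l_min=l_min, l_max=l_max, fallback=fallback)


def _fixed_thirds(R: int) -> tuple[int, int]:
    lo = max(1, R // 3)
    hi = min(R - 2, (2 * R) // 3)
    if hi <= lo:  # tiny R
        lo, hi = 0, R - 1
    return lo, hi


def band_distributions(clipped: ClippedCurve, bands: BandPartition
                       ) -> tuple[list[np.ndarray], list[np.ndarray], list[bool]]:
    """Per-band pdf and cdf of the clipped energy.

    Returns (pdfs, cdfs, zero_mass_flags), one entry per band in order.
    Each pdf is the band's clipped energy normalized by the band's total;
    a zero-mass band receives a uniform pdf over its levels and is flagged.
    """
    pdfs, cdfs, flags = [], [], []
    for a, b in bands.band_ranges():
        seg = clipped.values[a:b + 1]
        mass = seg.sum()
        if mass > 0:
            pdf = seg / mass
            flags.append(False)
        else:
            pdf = np.full(seg.shape, 1.0 / max(len(seg), 1))
            flags.append(True)
        pdfs.append(pdf)
        cdfs.append(np.cumsum(pdf))
    return pdfs, cdfs, flags


def build_transfer_function(bands: BandPartition,
                            cdfs: list[np.ndarray]) -> TransferFunction:
    """Assemble the piecewise transfer function from per-band cdfs.

    Each band [a, b] maps onto its own output interval via
    TrF(l) = a + round((b - a) * cdf(l)); the full function is the union of
    the three disjoint-support pieces, clamped to [0, R-1].  Mapping a band
    onto itself keeps the function range-preserving: no band can spill into
    a neighbor's output interval.
    """
    R = bands.R
    mapping = np.zeros(R, dtype=np.int64)
    for (a, b), cdf in zip(bands.band_ranges(), cdfs):
        if a > b:
            continue
        vals = a + np.floor((b - a) * cdf + 0.5)
        mapping[a:b + 1] = vals.astype(np.int64)
    mapping = np.clip(mapping, 0, R - 1)
    return TransferFunction(mapping=mapping, bands=bands)


def enhance_contrast(img: GrayImage, d: int = 1, f: float = 1.0,
                     report: dict | None = None) -> GrayImage:
    """Full context-aware enhancement: energy curve -> clip -> bands -> TrF.

    Deterministic end to end.  A constant image short-circuits through the
    degenerate path unchanged.  Pass a dict as ``report`` to collect stage
    flags (degenerate curve, band fallback, zero-mass bands) and the band
    boundaries.
    """
    curve = compute_energy_curve(img, d=d, f=f)
    clipped = clip_energy_curve(curve)
    if clipped.degenerate:
        if report is not None:
            report.update(degenerate_curve=True, fallback_bands=False,
                          zero_mass_bands=[], lo_low=None, lo_high=None)
        return img.copy()
    bands = partition_bands(clipped, img)
    pdfs, cdfs, zero_flags = band_distributions(clipped, bands)
    trf = build_transfer_function(bands, cdfs)
    if report is not None:
        report.update(degenerate_curve=False, fallback_bands=bands.fallback,
                      zero_mass_bands=[i for i, z in enumerate(zero_flags) if z],
                      lo_low=bands.lo_low, lo_high=bands.lo_high)
    return trf(img)
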