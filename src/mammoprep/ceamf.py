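"""Context/distance-adaptive median filtering for artifact and noise removal.

Mammograms commonly carry bright "light spot" artifacts — opaque labels,
embedded text, machine-induced marks — alongside impulsive pixel noise.  The
filter here removes both with a median whose window size grows near an
artifact and shrinks to the 3x3 minimum over clean tissue:

* inside a spot's effective radius ``a`` the window grows exponentially as
  the pixel approaches the center, ``U = 2*(exp(a/sdis) - 1) + 3``;
* outside, it grows only logarithmically with distance,
  ``U = 2*log10(sdis/a) + 3``;
* the result is clamped to odd integers in ``[u_min, S_dis]``, where the
  cap ``S_dis`` defaults to a quarter of the smallest spot dimension so the
  window never dwarfs the artifact it is erasing.

``sdis`` is the Euclidean distance to the nearest spot center and
``a = min(height, width) / 2`` that spot's effective radius.  Window medians
use the lower median so every output intensity is attained in the input,
and windows are clipped (not padded) at image borders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import GrayImage

__all__ = [
    "LightSpot", "WindowPolicy", "detect_light_spots", "spot_distance",
    "window_cap", "adaptive_window_size", "window_size_map", "apply_ceamf",
]


@dataclass(frozen=True)
class LightSpot:
    """A detected bright artifact: center (row, col), bounding-box extent.

    ``radius_a`` — the effective radius min(he, wi)/2 — is the boundary of
    the spot's influence: pixels closer than it use the exponential window
    branch, pixels beyond it the logarithmic one.
    """

    cen_y: int
    cen_x: int
    he: int
    wi: int

    def __post_init__(self):
        if self.he < 1 or self.wi < 1:
            raise ValueError(f"spot extent must be >= 1, got he={self.he}, wi={self.wi}")

    @property
    def radius_a(self) -> float:
        return min(self.he, self.wi) / 2.0


@dataclass(frozen=True)
class WindowPolicy:
    """Window-size limits: odd floor ``u_min``, odd cap ``s_dis``.

    ``default_cap_no_spots`` is the cap used when an image has no detected
    artifacts and the spot-derived cap of :func:`window_cap` is undefined.
    """

    u_min: int = 3
    s_dis: int = 9
    default_cap_no_spots: int = 9

    def __post_init__(self):
        if self.u_min < 3 or self.u_min % 2 == 0:
            raise ValueError(f"u_min must be an odd integer >= 3, got {self.u_min}")
        if self.s_dis < self.u_min or self.s_dis % 2 == 0:
            raise ValueError(f"s_dis must be an odd integer >= u_min, got {self.s_dis}")
        if self.default_cap_no_spots % 2 == 0 or self.default_cap_no_spots < 3:
            raise ValueError("default_cap_no_spots must be an odd integer >= 3")


def detect_light_spots(img: GrayImage, k_sigma: float = 2.5,
                       min_area: int = 16) -> list[LightSpot]:
    """Detect bright artifact regions by intensity thresholding.

    Pixels brighter than ``mean + k_sigma * std`` are grouped into
    8-connected components; components of at least ``min_area`` pixels become
    spots with extent from the bounding box and center from the centroid
    (rounded to the nearest pixel).  Spots are returned largest-area first.
    """
    pix = img.pixels.astype(np.float64)
    thresh = pix.mean() + k_sigma * pix.std()
    binary = pix > thresh
    if not binary.any():
        return []
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    spots: list[tuple[int, LightSpot]] = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        area = int((labels == lab).sum())
        if area < min_area:
            continue
        sl_y, sl_x = objects[lab - 1]
        cy, cx = ndimage.center_of_mass(labels == lab)
        spots.append((
            area,
            LightSpot(
                cen_y=int(math.floor(cy + 0.5)),
                cen_x=int(math.floor(cx + 0.5)),
                he=sl_y.stop - sl_y.start,
                wi=sl_x.stop - sl_x.start,
            ),
        ))
    spots.sort(key=lambda t: -t[0])
    return [s for _, s in spots]


def spot_distance(j: float, i: float, spot: LightSpot) -> float:
    """Euclidean distance from pixel (j, i) to the spot center."""
    return math.hypot(j - spot.cen_y, i - spot.cen_x)


def _odd_floor(x: float) -> int:
    """Largest odd integer <= x."""
    n = math.floor(x)
    return n if n % 2 == 1 else n - 1


def window_cap(spots: list[LightSpot], policy: WindowPolicy = WindowPolicy()) -> int:
    """Global window cap: a quarter of the smallest spot dimension, odd.

    Keeps even the largest filtering window smaller than the artifacts being
    removed.  With no spots the configured default applies.
    """
    if not spots:
        return policy.default_cap_no_spots
    min_dim = min(min(s.he, s.wi) for s in spots)
    cap = _odd_floor(min_dim / 4)
    return max(cap, policy.u_min)


def adaptive_window_size(j: float, i: float, spots: list[LightSpot],
                         policy: WindowPolicy = WindowPolicy()) -> int:
    """Window size at pixel (j, i): exponential inside the nearest spot's
    radius, logarithmic outside, clamped to odd values in [u_min, s_dis]."""
    if not spots:
        return policy.u_min
    sdis = min(spot_distance(j, i, s) for s in spots)
    nearest = min(spots, key=lambda s: spot_distance(j, i, s))
    a = nearest.radius_a
    if sdis == 0.0:
        return policy.s_dis  # the exponential branch's limit is the cap
    if sdis < a:
        u_raw = 2.0 * (math.exp(a / sdis) - 1.0) + 3.0
    else:
        u_raw = 2.0 * math.log10(sdis / a) + 3.0
    u = _odd_floor(min(u_raw, policy.s_dis))
    return max(policy.u_min, min(u, policy.s_dis))


def window_size_map(shape: tuple[int, int], spots: list[LightSpot],
                    policy: WindowPolicy = WindowPolicy()) -> np.ndarray:
    """Vectorized per-pixel window sizes for a whole image."""
    z, m = shape
    if not spots:
        return np.full((z, m), policy.u_min, dtype=np.int64)
    jj, ii = np.meshgrid(np.arange(z), np.arange(m), indexing="ij")
    dists = np.stack([
        np.hypot(jj - s.cen_y, ii - s.cen_x) for s in spots
    ])
    nearest_idx = dists.argmin(axis=0)
    sdis = dists.min(axis=0)
    radii = np.array([s.radius_a for s in spots])[nearest_idx]

    u_raw = np.empty((z, m), dtype=np.float64)
    zero = sdis == 0.0
    with np.errstate(divide="ignore", over="ignore"):
        inside = (~zero) & (sdis < radii)
        u_raw[inside] = 2.0 * (np.exp(radii[inside] / sdis[inside]) - 1.0) + 3.0
        outside = (~zero) & ~inside
        u_raw[outside] = 2.0 * np.log10(sdis[outside] / radii[outside]) + 3.0
    u_raw[zero] = policy.s_dis
    u_raw = np.minimum(u_raw, policy.s_dis)
    # largest odd integer <= u_raw, then clamp
    u = np.floor(u_raw).astype(np.int64)
    u = np.where(u % 2 == 0, u - 1, u)
    return np.clip(u, policy.u_min, policy.s_dis)


def _lower_median_filter(pixels: np.ndarray, umap: np.ndarray) -> np.ndarray:
    """Per-pixel lower median over border-clipped windows of size umap[j, i].

    Windows are materialized once per distinct window size using a
    NaN-padded sliding view; NaNs (out-of-bounds positions) sort to the end
    so the lower median of the valid count is a direct index.
    """
    out = np.empty_like(pixels)
    z, m = pixels.shape
    for u in np.unique(umap):
        u = int(u)
        r = (u - 1) // 2
        padded = np.full((z + 2 * r, m + 2 * r), np.nan)
        padded[r:z + r, r:m + r] = pixels
        windows = np.lib.stride_tricks.sliding_window_view(padded, (u, u))
        sel = umap == u
        w = windows[sel].reshape(sel.sum(), u * u)
        w = np.sort(w, axis=1)  # NaN sorts last
        n_valid = u * u - np.isnan(w).sum(axis=1)
        med = w[np.arange(w.shape[0]), (n_valid - 1) // 2]
        out[sel] = med.astype(pixels.dtype)
    return out


def apply_ceamf(img: GrayImage, spots: list[LightSpot] | None = None,
                policy: WindowPolicy | None = None,
                k_sigma: float = 2.5, min_area: int = 16) -> GrayImage:
    """Filter an image with the artifact-distance-adaptive median.

    Spots are detected internally when not supplied; the window cap defaults
    to :func:`window_cap` over the detected spots.  Output has the same
    shape and level count, and every output value is attained within the
    corresponding input window (lower median).
    """
    if spots is None:
        spots = detect_light_spots(img, k_sigma=k_sigma, min_area=min_area)
    if policy is None:
        base = WindowPolicy()
        cap = window_cap(spots, base)
        policy = WindowPolicy(u_min=base.u_min, s_dis=max(cap, base.u_min),
                              default_cap_no_spots=base.default_cap_no_spots)
    umap = window_size_map(img.shape, spots, policy)
    filtered = _lower_median_filter(img.pixels.astype(np.int64), umap)
    return GrayImage(filtered, img.levels)
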