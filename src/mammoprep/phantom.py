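"""Seeded synthetic mammogram-like phantoms, noise injection and perturbations.

The generator emulates the features the preprocessing chain must handle:
a smooth low-frequency breast-like textured background, an elliptical lesion
with a pixel-exact ground-truth mask, bright rectangular/elliptical artifact
"light spots" (labels, opacities), the five radiographic noise types
(gaussian, speckle, salt-and-pepper, quantum/Poisson, impulse), robustness
perturbations (added Gaussian noise, contrast reduction, resolution
degradation), multi-view cases (CC/MLO) and a 60/40 benign/malignant cohort
mix.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import BinaryMask, CaseRecord, GrayImage

__all__ = [
    "PhantomConfig", "NOISE_KINDS", "PERTURB_SCENARIOS",
    "generate_phantom_case", "inject_noise", "perturb", "generate_cohort",
]

NOISE_KINDS = ("gaussian", "speckle", "salt_pepper", "quantum", "impulse")
PERTURB_SCENARIOS = ("gaussian_low", "gaussian_medium",
                     "contrast_reduction", "downsample")


@dataclass
class LesionSpec:
    present: bool = True
    center: Optional[tuple[int, int]] = None  # (row, col); None -> near middle
    axes: tuple[int, int] = (20, 14)          # semi-axes in pixels
    intensity_boost: float = 0.25             # fraction of R added inside


@dataclass
class SpotSpec:
    count: int = 2
    size_range: tuple[int, int] = (16, 40)    # bounding-box side range, px


@dataclass
class NoiseSpec:
    kind: Optional[str] = None                # None -> clean image
    params: dict = field(default_factory=dict)


@dataclass
class PhantomConfig:
    """Configuration of one synthetic phantom view."""

    side: int = 256
    levels: int = 256
    background_smoothness: float = 12.0       # gaussian sigma of the texture
    lesion: LesionSpec = field(default_factory=LesionSpec)
    artifact_spots: SpotSpec = field(default_factory=SpotSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.side < 16:
            raise ValueError(f"side must be >= 16, got {self.side}")
        ay, ax = self.lesion.axes
        if self.lesion.present:
            cy, cx = self.lesion.center or (self.side // 2, self.side // 2)
            if not (ay <= cy < self.side - ay and ax <= cx < self.side - ax):
                raise ValueError(
                    f"lesion at ({cy},{cx}) axes {self.lesion.axes} exceeds "
                    f"the {self.side}x{self.side} image bounds"
                )
        lo, hi = self.artifact_spots.size_range
        if hi >= self.side // 2:
            raise ValueError("artifact spots too large for the image")


def _background(rng: np.random.Generator, side: int, levels: int,
                smoothness: float) -> np.ndarray:
    """Low-pass-filtered seeded noise scaled into the lower-mid level range."""
    raw = rng.standard_normal((side, side))
    smooth = ndimage.gaussian_filter(raw, sigma=smoothness, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    span = hi - lo if hi > lo else 1.0
    # breast tissue occupies roughly the 25%-55% intensity band
    return (0.25 + 0.30 * (smooth - lo) / span) * (levels - 1)


def _ellipse_mask(side: int, center: tuple[int, int],
                  axes: tuple[int, int]) -> np.ndarray:
    jj, ii = np.mgrid[0:side, 0:side]
    cy, cx = center
    ay, ax = axes
    return ((jj - cy) / ay) ** 2 + ((ii - cx) / ax) ** 2 <= 1.0


def generate_phantom_case(config: PhantomConfig) -> tuple[GrayImage, BinaryMask]:
    """Render one phantom view: background + lesion + artifact spots + noise.

    Returns the image and the lesion ground-truth mask (all zeros when no
    lesion is present).  Deterministic: identical config -> identical bits.
    """
    rng = np.random.default_rng(config.seed)
    side, levels = config.side, config.levels
    field_f = _background(rng, side, levels, config.background_smoothness)

    mask = np.zeros((side, side), dtype=np.uint8)
    if config.lesion.present:
        center = config.lesion.center or (side // 2, side // 2)
        ell = _ellipse_mask(side, center, config.lesion.axes)
        field_f[ell] += config.lesion.intensity_boost * (levels - 1)
        mask[ell] = 1

    lo_sz, hi_sz = config.artifact_spots.size_range
    for _ in range(config.artifact_spots.count):
        he = int(rng.integers(lo_sz, hi_sz + 1))
        wi = int(rng.integers(lo_sz, hi_sz + 1))
        cy = int(rng.integers(he // 2 + 1, side - he // 2 - 1))
        cx = int(rng.integers(wi // 2 + 1, side - wi // 2 - 1))
        if rng.random() < 0.5:  # rectangle
            field_f[cy - he // 2:cy + (he + 1) // 2,
                    cx - wi // 2:cx + (wi + 1) // 2] = 0.97 * (levels - 1)
        else:  # ellipse
            ell = _ellipse_mask(side, (cy, cx), (max(he // 2, 1), max(wi // 2, 1)))
            field_f[ell] = 0.97 * (levels - 1)

    img = GrayImage(np.clip(np.floor(field_f + 0.5), 0, levels - 1).astype(np.int64),
                    levels)
    if config.noise.kind is not None:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        img = inject_noise(img, config.noise.kind, config.noise.params, noise_seed)
    return img, BinaryMask(mask)


def inject_noise(img: GrayImage, kind: str, params: dict | None = None,
                 seed: int = 0) -> GrayImage:
    """Corrupt an image with one of the five radiographic noise types.

    gaussian    — additive N(0, (sigma*R)^2); param ``sigma`` as a fraction of R.
    speckle     — multiplicative y*(1 + N(0, sigma^2)); param ``sigma``.
    salt_pepper — a fraction ``rate`` of pixels set to 0 or R-1, split 50/50.
    quantum     — Poisson photon noise at ``photons`` expected counts at full
                  scale (shot noise grows with intensity, the radiographic
                  "quantum mottle").
    impulse     — a fraction ``rate`` of pixels replaced by uniform random levels.
    """
    if kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}; valid kinds: {NOISE_KINDS}")
    params = params or {}
    rng = np.random.default_rng(seed)
    pix = img.pixels.astype(np.float64)
    R = img.levels
    if kind == "gaussian":
        sigma = float(params.get("sigma", 0.05)) * (R - 1)
        if sigma == 0:
            return img.copy()
        out = pix + rng.normal(0.0, sigma, pix.shape)
    elif kind == "speckle":
        sigma = float(params.get("sigma", 0.1))
        if sigma == 0:
            return img.copy()
        out = pix * (1.0 + rng.normal(0.0, sigma, pix.shape))
    elif kind == "salt_pepper":
        rate = float(params.get("rate", 0.05))
        if rate == 0:
            return img.copy()
        out = pix.copy()
        hit = rng.random(pix.shape) < rate
        salt = rng.random(pix.shape) < 0.5
        out[hit & salt] = R - 1
        out[hit & ~salt] = 0
    elif kind == "quantum":
        photons = float(params.get("photons", 200.0))
        expected = pix / (R - 1) * photons
        counts = rng.poisson(expected)
        out = counts / photons * (R - 1)
    else:  # impulse
        rate = float(params.get("rate", 0.05))
        if rate == 0:
            return img.copy()
        out = pix.copy()
        hit = rng.random(pix.shape) < rate
        out[hit] = rng.integers(0, R, size=int(hit.sum()))
    out = np.clip(np.floor(out + 0.5), 0, R - 1).astype(np.int64)
    return GrayImage(out, R)


def perturb(img: GrayImage, scenario: str, seed: int = 0) -> GrayImage:
    """Apply a robustness perturbation scenario.

    gaussian_low / gaussian_medium — additive Gaussian noise at sigma 0.05*R
    and 0.10*R; contrast_reduction — deviations from the image mean scaled by
    0.85; downsample — 2x block-mean downsampling then nearest-neighbor
    upsampling back to the original size.
    """
    if scenario == "gaussian_low":
        return inject_noise(img, "gaussian", {"sigma": 0.05}, seed)
    if scenario == "gaussian_medium":
        return inject_noise(img, "gaussian", {"sigma": 0.10}, seed)
    if scenario == "contrast_reduction":
        pix = img.pixels.astype(np.float64)
        mean = pix.mean()
        out = mean + 0.85 * (pix - mean)
        out = np.clip(np.floor(out + 0.5), 0, img.levels - 1).astype(np.int64)
        return GrayImage(out, img.levels)
    if scenario == "downsample":
        pix = img.pixels.astype(np.float64)
        z, m = pix.shape
        z2, m2 = z - z % 2, m - m % 2
        blocks = pix[:z2, :m2].reshape(z2 // 2, 2, m2 // 2, 2).mean(axis=(1, 3))
        up = np.repeat(np.repeat(blocks, 2, axis=0), 2, axis=1)
        out = pix.copy()
        out[:z2, :m2] = up
        out = np.clip(np.floor(out + 0.5), 0, img.levels - 1).astype(np.int64)
        return GrayImage(out, img.levels)
    raise ValueError(f"unknown perturbation scenario {scenario!r}; "
                     f"valid scenarios: {PERTURB_SCENARIOS}")


def generate_cohort(n_cases: int, benign_fraction: float = 0.60,
                    views: tuple[str, ...] = ("CC", "MLO"),
                    laterality: str = "L",
                    base_config: PhantomConfig | None = None,
                    seed: int = 0,
                    materialize: bool = False) -> list[CaseRecord]:
    """Generate a synthetic cohort of multi-view cases with a fixed class mix.

    Exactly ``round(n_cases * benign_fraction)`` cases are benign (no
    lesion); the rest are malignant and carry a lesion whose pixels form the
    ground-truth mask.  Views of one case share the case's label and a
    per-case seed lineage.  With ``materialize=False`` only the manifest
    structure is produced (image_ref holds the per-view PhantomConfig's
    rendered image lazily skipped); with ``materialize=True`` images and
    masks are rendered in memory.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not (0.0 < benign_fraction < 1.0):
        raise ValueError("benign_fraction must be in (0, 1)")
    base = base_config or PhantomConfig()
    n_benign = int(np.floor(n_cases * benign_fraction + 0.5))
    rng = np.random.default_rng(seed)
    labels = np.array(["benign"] * n_benign
                      + ["malignant"] * (n_cases - n_benign))
    rng.shuffle(labels)
    records: list[CaseRecord] = []
    for idx, label in enumerate(labels):
        case_id = f"case{idx:05d}"
        case_seed = int(rng.integers(0, 2**31 - 1))
        for v_i, view in enumerate(views):
            cfg = copy.deepcopy(base)
            cfg.seed = case_seed * 8 + v_i
            cfg.lesion.present = label == "malignant"
            if label == "malignant" and cfg.lesion.center is None:
                ay, ax = cfg.lesion.axes
                if base.side <= 2 * max(ay, ax):
                    raise ValueError("lesion axes too large for the image side")
                crng = np.random.default_rng(cfg.seed)
                cfg.lesion.center = (int(crng.integers(ay, base.side - ay)),
                                     int(crng.integers(ax, base.side - ax)))
            image_ref = mask_ref = None
            if materialize:
                image_ref, mask_ref = generate_phantom_case(cfg)
            records.append(CaseRecord(
                case_id=case_id, laterality=laterality, view=view,
                label=str(label), image_ref=image_ref, mask_ref=mask_ref,
            ))
    return records
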