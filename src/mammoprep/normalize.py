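"""Z-score intensity normalization and re-quantization to integer levels.

Centering by the image mean and scaling by the population standard deviation
(divisor N) puts every denoised mammogram on a comparable intensity scale.
Because the contrast-enhancement stage operates on discrete gray levels, the
real-valued z-scores are re-quantized onto [0, R-1] with a min-max affine
map before that stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GrayImage

__all__ = ["RealImage", "zscore_normalize", "requantize"]


@dataclass
class RealImage:
    """A real-valued image, typically the z-scored form of a GrayImage.

    ``degenerate`` is set when the source image had zero variance (the
    z-score is then defined as identically zero).
    """

    pixels: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("real image must contain only finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def zscore_normalize(img: GrayImage) -> RealImage:
    """Z-score an image: (y - mean) / population std.

    A constant image (std = 0) yields all zeros with the degenerate flag set
    rather than an error, so batch pipelines survive blank frames.
    """
    if img.pixels.size < 2:
        raise ValueError("z-score normalization needs at least 2 pixels")
    pix = img.pixels.astype(np.float64)
    mean = pix.mean()
    std = pix.std()  # population (1/N) divisor
    if std == 0.0:
        return RealImage(np.zeros_like(pix), degenerate=True)
    return RealImage((pix - mean) / std)


def requantize(img: RealImage, R: int = 256) -> GrayImage:
    """Min-max map a real image onto integer levels [0, R-1], round half-up.

    Constant input maps to level 0.  The map is invariant to positive affine
    transforms of the input, so the z-score's scale convention cannot affect
    downstream contrast enhancement.
    """
    if R < 2:
        raise ValueError(f"R must be >= 2, got {R}")
    pix = img.pixels
    lo, hi = pix.min(), pix.max()
    if hi == lo:
        return GrayImage(np.zeros(pix.shape, dtype=np.int64), R)
    scaled = (pix - lo) / (hi - lo) * (R - 1)
    q = np.clip(np.floor(scaled + 0.5), 0, R - 1).astype(np.int64)
    return GrayImage(q, R)
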