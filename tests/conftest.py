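import numpy as np
import pytest

from mammoprep import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def random_images(rng):
    """A batch of small random 8-bit images of assorted shapes."""
    shapes = [(4, 4), (7, 5), (12, 12), (9, 16), (32, 32)]
    return [GrayImage(rng.integers(0, 256, size=s), 256) for s in shapes]


def naive_energy_curve(pixels: np.ndarray, R: int, d: int = 1, f: float = 1.0) -> np.ndarray:
    """Independent per-level oracle: threshold to +/-1 fields and sum
    weighted neighbor products directly."""
    z, m = pixels.shape
    offsets = [(dy, dx) for dy in range(-d, d + 1) for dx in range(-d, d + 1)
               if (dy, dx) != (0, 0)]
    energy = np.zeros(R)
    for level in range(R):
        b = np.where(pixels > level, 1.0, -1.0)
        corr = 0.0
        const = 0.0
        for j in range(z):
            for i in range(m):
                for dy, dx in offsets:
                    q, w = j + dy, i + dx
                    if 0 <= q < z and 0 <= w < m:
                        wgt = (1.0 / max(abs(dy), abs(dx))) ** f
                        corr += wgt * b[j, i] * b[q, w]
                        const += wgt
        energy[level] = -corr + const
    return energy


def naive_adaptive_median(pixels: np.ndarray, umap: np.ndarray) -> np.ndarray:
    """Independent per-pixel lower-median oracle over border-clipped windows."""
    z, m = pixels.shape
    out = np.empty_like(pixels)
    for j in range(z):
        for i in range(m):
            r = (int(umap[j, i]) - 1) // 2
            window = pixels[max(0, j - r):min(z, j + r + 1),
                            max(0, i - r):min(m, i + r + 1)].ravel()
            vals = np.sort(window)
            out[j, i] = vals[(len(vals) - 1) // 2]
    return out
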