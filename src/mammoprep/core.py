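"""Core image/mask/manifest types, readers/writers and geometric standardization.

Images are 2-D integer intensity grids with an explicit gray-level count ``R``
(256 for 8-bit sources, 65536 for 16-bit).  Coordinates are 0-based
``(row, column)`` with row 0 at the top.  Masks are strictly binary {0, 1}
grids; on disk they are 8-bit PNGs with 0 = background and 255 = foreground.
Cohort manifests are comma-delimited UTF-8 with header
``case_id,laterality,view,label,image_path[,mask_path][,split]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "GrayImage", "BinaryMask", "CaseRecord", "ManifestError",
    "read_image", "write_image", "read_mask", "write_mask",
    "read_manifest", "write_manifest", "standardize_image",
]

LATERALITIES = ("L", "R")
VIEWS = ("CC", "MLO")
LABELS = ("benign", "malignant")

MANIFEST_COLUMNS = ["case_id", "laterality", "view", "label", "image_path"]


class ManifestError(ValueError):
    """Raised when a cohort manifest violates the case-record invariants.

    Carries every offending row, not just the first one found.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "manifest validation failed:\n  " + "\n  ".join(self.violations)
        )


@dataclass
class GrayImage:
    """A 2-D grayscale image with ``levels`` discrete intensities.

    Every pixel lies in ``[0, levels - 1]``.  ``pixels`` is an integer numpy
    array of shape ``(height, width)``.
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.pixels.shape}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError(f"image pixels must be integers, got {self.pixels.dtype}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.pixels.size and (
            int(self.pixels.min()) < 0 or int(self.pixels.max()) > self.levels - 1
        ):
            raise ValueError(
                f"pixel values outside [0, {self.levels - 1}]: "
                f"range [{self.pixels.min()}, {self.pixels.max()}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "GrayImage":
        return GrayImage(self.pixels.copy(), self.levels)


@dataclass
class BinaryMask:
    """A binary {0, 1} mask, shape-matched to its paired image."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.pixels.shape}")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class CaseRecord:
    """One view of a patient case; the case_id is the unit of data splitting.

    ``image_ref``/``mask_ref`` may be filesystem paths or in-memory objects
    so synthetic cohorts never need to touch disk.
    """

    case_id: str
    laterality: str
    view: str
    label: str
    image_ref: Union[str, Path, GrayImage, None] = None
    mask_ref: Union[str, Path, BinaryMask, None] = None
    split: Optional[str] = None

    def __post_init__(self):
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def load_image(self) -> GrayImage:
        if isinstance(self.image_ref, GrayImage):
            return self.image_ref
        if self.image_ref is None:
            raise ValueError(f"case {self.case_id}: no image attached")
        return read_image(self.image_ref)

    def load_mask(self) -> Optional[BinaryMask]:
        if self.mask_ref is None:
            return None
        if isinstance(self.mask_ref, BinaryMask):
            return self.mask_ref
        return read_mask(self.mask_ref)


# ---------------------------------------------------------------------------
# image I/O


def _levels_for_dtype(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 256
    if dtype == np.uint16:
        return 65536
    raise ValueError(f"unsupported grayscale dtype {dtype}; expected uint8 or uint16")


def read_image(path: Union[str, Path], format: Optional[str] = None) -> GrayImage:
    """Read a PNG, TIFF or DICOM file into a :class:`GrayImage`.

    The level count is inferred from bit depth (8-bit -> 256, 16-bit ->
    65536).  DICOM pixel data are rescaled by slope/intercept and quantized
    back to the level range declared by the stored bit depth.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt in ("DCM", "DICOM"):
        return _read_dicom(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(
                f"{path} has {arr.shape[2]} channels; convert to single-channel "
                "grayscale before reading"
            )
    levels = _levels_for_dtype(arr.dtype)
    return GrayImage(arr.astype(np.int64), levels)


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"{path}: only single-frame grayscale DICOM is supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    real = arr.astype(np.float64) * slope + intercept
    bits = int(getattr(ds, "BitsStored", 16))
    levels = 256 if bits <= 8 else 65536
    q = np.clip(np.floor(real + 0.5), 0, levels - 1).astype(np.int64)
    return GrayImage(q, levels)


def write_image(img: GrayImage, path: Union[str, Path]) -> None:
    """Write a :class:`GrayImage` as PNG or TIFF, 8- or 16-bit by level count."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".png", ".tif", ".tiff"):
        raise ValueError(f"write_image supports PNG/TIFF only, got {suffix!r}")
    dtype = np.uint8 if img.levels <= 256 else np.uint16
    arr = img.pixels.astype(dtype)
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path: Union[str, Path]) -> BinaryMask:
    """Read an 8-bit PNG mask; values > 127 become foreground."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read mask: no such file {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask((arr > 127).astype(np.uint8))


def write_mask(mask: BinaryMask, path: Union[str, Path]) -> None:
    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# geometric standardization


def standardize_image(img: GrayImage, side: int = 1024) -> GrayImage:
    """Resize to ``side x side``, padding to square with level 0 first.

    Padding (bottom/right, black) preserves the aspect ratio of the breast
    content; the padded square is then rescaled bilinearly and rounded back
    to integer levels.  The operation is deterministic and an identity when
    the input is already ``side x side``.
    """
    if side < 2:
        raise ValueError(f"side must be >= 2, got {side}")
    if img.shape == (side, side):
        return img.copy()
    h, w = img.shape
    dim = max(h, w)
    padded = np.zeros((dim, dim), dtype=np.float64)
    padded[:h, :w] = img.pixels
    out = _sk_resize(padded, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    out = np.clip(np.floor(out + 0.5), 0, img.levels - 1).astype(np.int64)
    return GrayImage(out, img.levels)


# ---------------------------------------------------------------------------
# manifests


def read_manifest(path: Union[str, Path]) -> list[CaseRecord]:
    """Parse a cohort manifest CSV into validated :class:`CaseRecord` rows.

    All invariant violations (duplicate case/laterality/view keys, label
    conflicts within a case, bad enumeration values) are collected and
    reported together in a single :class:`ManifestError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such manifest {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError([f"missing required columns: {missing}"])
    violations: list[str] = []
    records: list[CaseRecord] = []
    seen: dict[tuple, int] = {}
    case_labels: dict[str, str] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        key = (row["case_id"], row["laterality"], row["view"])
        if key in seen:
            violations.append(
                f"row {rowno}: duplicate (case_id, laterality, view) {key} "
                f"first seen at row {seen[key]}"
            )
        else:
            seen[key] = rowno
        prior = case_labels.get(row["case_id"])
        if prior is not None and prior != row["label"]:
            violations.append(
                f"row {rowno}: case {row['case_id']!r} labeled {row['label']!r} "
                f"but earlier rows say {prior!r}"
            )
        else:
            case_labels.setdefault(row["case_id"], row["label"])
        try:
            records.append(
                CaseRecord(
                    case_id=row["case_id"],
                    laterality=row["laterality"],
                    view=row["view"],
                    label=row["label"],
                    image_ref=row["image_path"] or None,
                    mask_ref=row.get("mask_path") or None,
                    split=row.get("split") or None,
                )
            )
        except ValueError as exc:
            violations.append(f"row {rowno}: {exc}")
    if violations:
        raise ManifestError(violations)
    return records


def write_manifest(cases: list[CaseRecord], path: Union[str, Path]) -> None:
    """Write case records back to manifest CSV (paths only, not in-memory data)."""
    rows = []
    for c in cases:
        rows.append({
            "case_id": c.case_id,
            "laterality": c.laterality,
            "view": c.view,
            "label": c.label,
            "image_path": str(c.image_ref) if isinstance(c.image_ref, (str, Path)) else "",
            "mask_path": str(c.mask_ref) if isinstance(c.mask_ref, (str, Path)) else "",
            "split": c.split or "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)
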