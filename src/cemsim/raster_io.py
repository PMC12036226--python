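"""Image, mask and annotation-table I/O plus basic breast-region preprocessing.

Contrast-enhanced mammography (CEM) exams are handled as pairs of 2D grayscale
rasters: a *low-energy* image (equivalent to a digital mammogram, showing
breast architecture and calcifications) and a *recombined* image (weighted
subtraction highlighting iodine uptake). Images travel as 16-bit grayscale
PNG; binary masks as 8-bit {0, 255} PNG; ROI annotation tables as CSV.

All rasters are row-major with a 0-based origin in the top-left corner and an
isotropic pixel pitch in millimetres.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import exposure, filters


class View(str, enum.Enum):
    """Mammographic projection."""

    CC = "CC"
    MLO = "MLO"


class ImageKind(str, enum.Enum):
    LOW_ENERGY = "low_energy"
    RECOMBINED = "recombined"


class Laterality(str, enum.Enum):
    L = "L"
    R = "R"


@dataclasses.dataclass
class GrayImage:
    """A 2D nonnegative intensity raster with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        2D array of finite, nonnegative intensities (float64 internally).
    spacing_mm : float
        Isotropic pixel pitch in millimetres; must be positive.
    view : View
        Mammographic projection (CC or MLO).
    kind : ImageKind
        Whether this is the low-energy or the recombined image.
    """

    pixels: np.ndarray
    spacing_mm: float
    view: View
    kind: ImageKind

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D raster")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        self.view = View(self.view)
        self.kind = ImageKind(self.kind)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def copy_with(self, pixels: np.ndarray) -> "GrayImage":
        return GrayImage(pixels=pixels, spacing_mm=self.spacing_mm,
                         view=self.view, kind=self.kind)


@dataclasses.dataclass
class CaseImagePair:
    """Low-energy + recombined images of one breast in one view."""

    low_energy: GrayImage
    recombined: GrayImage
    patient_id: str = "anonymous"
    laterality: Laterality = Laterality.L

    def __post_init__(self) -> None:
        if self.low_energy.shape != self.recombined.shape:
            raise ValueError("paired images must share a shape")
        if self.low_energy.spacing_mm != self.recombined.spacing_mm:
            raise ValueError("paired images must share pixel spacing")
        if self.low_energy.view != self.recombined.view:
            raise ValueError("paired images must share the view")
        self.laterality = Laterality(self.laterality)


@dataclasses.dataclass
class BreastMask:
    """Binary raster marking the breast region of a GrayImage."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")


@dataclasses.dataclass
class RoiRecord:
    """One annotated or predicted region of interest.

    ``mask`` may be an in-memory boolean raster or a path reference to a mask
    PNG; ``score`` is present only for predictions.
    """

    patient_id: str
    view: View
    mask: Union[np.ndarray, str, Path]
    label: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        self.view = View(self.view)
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


# ---------------------------------------------------------------------------
# PNG image / mask I/O
# ---------------------------------------------------------------------------

def read_image(path, spacing_mm: float, view, kind) -> GrayImage:
    """Read an 8/16-bit grayscale PNG into a :class:`GrayImage`.

    The raster is loaded without any lossy conversion; 16-bit depth is
    preserved. An RGB(A) file in a grayscale slot is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA", "P", "CMYK"):
            raise ValueError(f"expected grayscale PNG, got mode {im.mode!r}: {path}")
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel raster: {path}")
    return GrayImage(pixels=arr.astype(np.float64), spacing_mm=spacing_mm,
                     view=view, kind=kind)


def write_image(path, img: GrayImage) -> None:
    """Write a GrayImage as 16-bit grayscale PNG (values rounded, clipped)."""
    arr = np.clip(np.rint(img.pixels), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(Path(path), format="PNG")


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG as a boolean raster (any nonzero = True)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel mask: {path}")
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean raster as an 8-bit {0, 255} PNG."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


# ---------------------------------------------------------------------------
# Breast segmentation
# ---------------------------------------------------------------------------

def segment_breast(img: GrayImage) -> BreastMask:
    """Segment the breast as the largest bright component touching a lateral border.

    Otsu threshold -> largest connected component -> hole fill. A uniformly
    bright image yields a full-frame mask; an all-zero image raises.
    """
    px = img.pixels
    if np.all(px <= 0):
        raise ValueError("no breast found: image has empty foreground")
    lo, hi = float(px.min()), float(px.max())
    if hi - lo < 1e-12:
        # uniformly bright: no contrast to threshold, whole frame is breast
        return BreastMask(mask=np.ones_like(px, dtype=bool))
    thr = filters.threshold_otsu(px)
    fg = px > thr
    if not fg.any():
        raise ValueError("no breast found: empty foreground after threshold")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = np.argmax(sizes) + 1
    comp = labels == largest
    comp = ndimage.binary_fill_holes(comp)
    return BreastMask(mask=comp)


# ---------------------------------------------------------------------------
# CLAHE channel composition
# ---------------------------------------------------------------------------

def _clahe(pixels: np.ndarray, tiles: int, clip_limit: float) -> np.ndarray:
    """CLAHE on an arbitrary-range raster, returned in [0, 1]."""
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi - lo < 1e-12:
        # constant image: nothing to equalize
        return np.zeros_like(pixels, dtype=np.float64)
    norm = (pixels - lo) / (hi - lo)
    kernel = (max(pixels.shape[0] // tiles, 1), max(pixels.shape[1] // tiles, 1))
    return exposure.equalize_adapthist(norm, kernel_size=kernel, clip_limit=clip_limit)


def compose_rgb(pair: CaseImagePair, tiles: int = 8, clip_limit: float = 0.01) -> np.ndarray:
    """Compose the 3-channel preprocessing stack for a CEM pair.

    Channel 1 is the CLAHE-filtered low-energy image, channel 2 the original
    low-energy image untouched, channel 3 the CLAHE-filtered recombined image.
    This weighting favours the low-energy image, in which microcalcifications
    are visible. CLAHE channels are in [0, 1]; channel 2 keeps the raw values
    so no information is lost. Returns an (H, W, 3) float array.
    """
    c1 = _clahe(pair.low_energy.pixels, tiles, clip_limit)
    c2 = pair.low_energy.pixels
    c3 = _clahe(pair.recombined.pixels, tiles, clip_limit)
    return np.stack([c1, c2, c3], axis=-1)


def write_rgb(path, stack: np.ndarray) -> None:
    """Export a composed 3-channel stack as an 8-bit RGB PNG.

    Each channel is scaled to [0, 255] independently (channel 2 carries the
    raw dynamic range and must be brought into display range).
    """
    out = np.empty(stack.shape, dtype=np.uint8)
    for c in range(3):
        ch = stack[..., c]
        lo, hi = float(ch.min()), float(ch.max())
        scale = 255.0 / (hi - lo) if hi - lo > 1e-12 else 0.0
        out[..., c] = np.clip(np.rint((ch - lo) * scale), 0, 255).astype(np.uint8)
    Image.fromarray(out, mode="RGB").save(Path(path), format="PNG")


# ---------------------------------------------------------------------------
# ROI annotation tables
# ---------------------------------------------------------------------------

ROI_TABLE_COLUMNS = ["patient_id", "view", "mask_path", "label", "score"]


def write_roi_table(path, records: list) -> None:
    """Write RoiRecords (with path-valued masks) to a CSV annotation table."""
    rows = []
    for r in records:
        if isinstance(r.mask, np.ndarray):
            raise ValueError("write_roi_table requires mask path references")
        rows.append({"patient_id": r.patient_id, "view": r.view.value,
                     "mask_path": str(r.mask), "label": r.label,
                     "score": r.score if r.score is not None else np.nan})
    pd.DataFrame(rows, columns=ROI_TABLE_COLUMNS).to_csv(path, index=False)


def read_roi_table(path) -> list:
    """Read a CSV annotation table into RoiRecords (masks stay as paths)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        score = row.get("score", np.nan)
        records.append(RoiRecord(
            patient_id=str(row["patient_id"]), view=View(row["view"]),
            mask=str(row["mask_path"]), label=str(row["label"]),
            score=None if pd.isna(score) else float(score)))
    return records
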