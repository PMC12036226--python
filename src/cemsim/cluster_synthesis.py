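"""Candidate calcification extraction and microcalcification-cluster growth.

Within the selected grid cell, a binary candidate mask is formed as the
logical AND of (i) a binarized Frangi vesselness response — calcifications
tend to follow the curvilinear structures of the breast tissue — and (ii) an
intensity-threshold mask keeping the locally bright pixels. Connected regions
of the candidate mask are measured (area, marching-squares perimeter,
circularity 4*pi*A/P^2, equivalent diameter in mm) and filtered by
class-specific morphology:

* typically benign clusters keep the larger, rounder calcifications
  (circularity in [0.5, 1.0], equivalent diameter in [0.3, 1.2] mm) and
  contain 10–20 calcifications;
* typically malignant clusters keep small calcifications of any shape
  (diameter in [0.1, 0.5] mm, any circularity) and contain 20–40.

Cluster growth starts from the highest-contrast 10x10-px sub-cell and expands
the search window one sub-cell ring at a time, accumulating filtered regions
until a target count (drawn uniformly from the class range) is reached. If
the cell cannot supply even the class minimum, the view is reported
infeasible and skipped by the caller.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .site_selection import GridCell


class LesionClass(str, enum.Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class InfeasibleClusterError(RuntimeError):
    """Raised when too few candidate regions satisfy the class criteria."""


@dataclasses.dataclass
class ClassCriteria:
    """Morphology and count criteria for one cluster class (closed intervals)."""

    lesion_class: LesionClass
    circularity_range: Tuple[float, float]
    size_range_mm: Tuple[float, float]
    count_range: Tuple[int, int]

    @classmethod
    def benign(cls) -> "ClassCriteria":
        return cls(LesionClass.BENIGN, (0.5, 1.0), (0.3, 1.2), (10, 20))

    @classmethod
    def malignant(cls) -> "ClassCriteria":
        return cls(LesionClass.MALIGNANT, (0.0, 1.0), (0.1, 0.5), (20, 40))

    @classmethod
    def for_class(cls, lesion_class) -> "ClassCriteria":
        lesion_class = LesionClass(lesion_class)
        return cls.benign() if lesion_class is LesionClass.BENIGN else cls.malignant()


@dataclasses.dataclass
class CandidateRegion:
    """One connected candidate region, measured in within-cell coordinates."""

    pixels: np.ndarray          # (n, 2) array of (row, col) within-cell coords
    area_px: int
    perimeter_px: float
    circularity: float
    equivalent_diameter_mm: float
    mean_intensity: float
    centroid: Tuple[float, float]
    bbox_topleft: Tuple[int, int]


# ---------------------------------------------------------------------------
# Candidate mask
# ---------------------------------------------------------------------------

def candidate_mask(cell: np.ndarray,
                   frangi_sigmas: Sequence[float] = (2.0, 4.0, 6.0),
                   frangi_percentile: float = 90.0,
                   intensity_nstd: float = 1.0) -> np.ndarray:
    """Binary candidate mask: Frangi-response mask AND intensity-threshold mask.

    The vesselness response is binarized at ``frangi_percentile`` of its
    within-cell distribution; the intensity mask keeps pixels above
    mean + ``intensity_nstd`` * std of the cell. A structureless (constant)
    cell yields an empty mask.
    """
    cell = np.asarray(cell, dtype=np.float64)
    if cell.size == 0:
        raise ValueError("empty cell raster")
    if cell.max() - cell.min() < 1e-12:
        return np.zeros_like(cell, dtype=bool)
    response = filters.frangi(cell, sigmas=frangi_sigmas, black_ridges=False)
    thr_f = np.percentile(response, frangi_percentile)
    frangi_mask = response > thr_f
    thr_i = cell.mean() + intensity_nstd * cell.std()
    intensity_mask = cell > thr_i
    return frangi_mask & intensity_mask


# ---------------------------------------------------------------------------
# Region extraction and measurement
# ---------------------------------------------------------------------------

def _marching_perimeter(region_mask: np.ndarray) -> float:
    """Contour length of a region via marching squares on the padded mask.

    Measuring the iso-0.5 contour reduces the staircase bias of pixel-edge
    perimeters, keeping circularity of rasterized discs near 1.
    """
    padded = np.pad(region_mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        total += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    return total


def extract_candidates(mask: np.ndarray, spacing_mm: float) -> List[CandidateRegion]:
    """Measure all 8-connected regions of a binary mask.

    Regions are ordered by the (top, left) of their bounding boxes. The
    equivalent diameter is ``2 * spacing * sqrt(area / pi)`` (mm); circularity
    ``4*pi*A/P^2`` is clipped to 1.0 because the sub-pixel perimeter of very
    small rasterized regions can fall below that of the equal-area disc.
    """
    mask = np.asarray(mask, dtype=bool)
    if not spacing_mm > 0:
        raise ValueError("spacing_mm must be positive")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    regions: List[CandidateRegion] = []
    for lab in range(1, n + 1):
        region = labels == lab
        coords = np.argwhere(region)
        area = int(coords.shape[0])
        sub = region[coords[:, 0].min():coords[:, 0].max() + 1,
                     coords[:, 1].min():coords[:, 1].max() + 1]
        perim = _marching_perimeter(sub)
        circ = min(1.0, 4.0 * np.pi * area / perim ** 2) if perim > 0 else 1.0
        regions.append(CandidateRegion(
            pixels=coords,
            area_px=area,
            perimeter_px=perim,
            circularity=float(circ),
            equivalent_diameter_mm=float(2.0 * spacing_mm * np.sqrt(area / np.pi)),
            mean_intensity=0.0,
            centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
            bbox_topleft=(int(coords[:, 0].min()), int(coords[:, 1].min())),
        ))
    regions.sort(key=lambda r: r.bbox_topleft)
    return regions


def attach_intensities(regions: List[CandidateRegion], cell: np.ndarray) -> None:
    """Fill each region's mean intensity from the cell raster (in place)."""
    for r in regions:
        r.mean_intensity = float(cell[r.pixels[:, 0], r.pixels[:, 1]].mean())


def filter_candidates(regions: Sequence[CandidateRegion],
                      criteria: ClassCriteria) -> List[CandidateRegion]:
    """Keep regions whose circularity and size lie inside the closed class ranges."""
    c_lo, c_hi = criteria.circularity_range
    s_lo, s_hi = criteria.size_range_mm
    return [r for r in regions
            if c_lo <= r.circularity <= c_hi
            and s_lo <= r.equivalent_diameter_mm <= s_hi]


# ---------------------------------------------------------------------------
# Cluster growth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterModel:
    """2D binary cluster model at the resolution of the low-energy image.

    ``raster`` has 1 where a calcification is present and 0 elsewhere; every
    calcification pixel lies inside the anchor cell's bounds.
    """

    raster: np.ndarray
    lesion_class: LesionClass
    count: int
    anchor: GridCell
    members: List[CandidateRegion]

    @property
    def support(self) -> np.ndarray:
        return self.raster.astype(bool)


def _subcell_contrast(cell: np.ndarray, subcell_px: int) -> np.ndarray:
    """Per-sub-cell contrast (max - mean) over the regular sub-grid."""
    n = cell.shape[0] // subcell_px
    m = cell.shape[1] // subcell_px
    blocks = cell[:n * subcell_px, :m * subcell_px].reshape(
        n, subcell_px, m, subcell_px).transpose(0, 2, 1, 3)
    return blocks.max(axis=(2, 3)) - blocks.mean(axis=(2, 3))


def grow_cluster(cell: np.ndarray, regions: Sequence[CandidateRegion],
                 criteria: ClassCriteria, anchor: GridCell,
                 image_shape: Tuple[int, int], subcell_px: int = 10,
                 seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None) -> ClusterModel:
    """Grow a cluster from the highest-contrast sub-cell of the selected cell.

    ``regions`` must already satisfy the class morphology criteria. The target
    calcification count is drawn uniformly from the class count range. The
    search window starts at the winning sub-cell and expands by one sub-cell
    ring per iteration; regions whose centroid falls inside the window are
    added in deterministic (top, left) order until the target is reached. If
    the cell is exhausted below the class minimum, the cluster is infeasible.
    """
    if cell.shape[0] % subcell_px or cell.shape[1] % subcell_px:
        raise ValueError("subcell_px must divide the cell size")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = criteria.count_range
    target = int(rng.integers(lo, hi + 1))

    contrast = _subcell_contrast(cell, subcell_px)
    flat = np.argmax(contrast)   # ties resolve to first (row-major) sub-cell
    sr, sc = np.unravel_index(flat, contrast.shape)
    n_rows, n_cols = contrast.shape

    ordered = sorted(regions, key=lambda r: r.bbox_topleft)
    chosen: List[CandidateRegion] = []
    chosen_ids = set()
    ring = 0
    max_ring = max(sr, n_rows - 1 - sr, sc, n_cols - 1 - sc)
    while len(chosen) < target:
        r0 = max(sr - ring, 0) * subcell_px
        c0 = max(sc - ring, 0) * subcell_px
        r1 = (min(sr + ring, n_rows - 1) + 1) * subcell_px
        c1 = (min(sc + ring, n_cols - 1) + 1) * subcell_px
        for reg in ordered:
            if id(reg) in chosen_ids:
                continue
            cy, cx = reg.centroid
            if r0 <= cy < r1 and c0 <= cx < c1:
                chosen.append(reg)
                chosen_ids.add(id(reg))
                if len(chosen) >= target:
                    break
        if len(chosen) >= target or ring >= max_ring:
            break
        ring += 1

    if len(chosen) < lo:
        raise InfeasibleClusterError(
            f"only {len(chosen)} candidate regions satisfy the "
            f"{criteria.lesion_class.value} criteria (need >= {lo}); "
            "no simulation for this view")

    raster = np.zeros(image_shape, dtype=np.uint8)
    r_off, c_off = anchor.bounds[0], anchor.bounds[1]
    for reg in chosen:
        raster[reg.pixels[:, 0] + r_off, reg.pixels[:, 1] + c_off] = 1
    return ClusterModel(raster=raster, lesion_class=criteria.lesion_class,
                        count=len(chosen), anchor=anchor, members=chosen)
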