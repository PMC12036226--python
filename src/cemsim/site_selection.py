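"""Grid-based texture ranking to locate a plausible lesion-insertion site.

The low-energy image is tiled into non-overlapping square cells (200x200 px by
default), anchored at the image origin. Texture features are computed per cell
restricted to cells lying (almost) fully inside the breast, and cells are
ranked feature-by-feature; the weighted rank-sum winner is taken as the most
plausible insertion location — a dense region with high structural variety,
where a microcalcification cluster would plausibly develop.

The exact radiomics feature set used on clinical data is not fixed by the
method; this module ships five standard texture proxies (mean intensity,
standard deviation, intensity entropy, mean gradient magnitude, local range),
each with a configurable direction and weight, as a documented, replaceable
default.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Dict, List, Sequence

import numpy as np
from scipy import ndimage, stats

from .raster_io import BreastMask, GrayImage


class Direction(str, enum.Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


@dataclasses.dataclass
class FeatureSpec:
    """Ranking direction and weight for one named cell feature."""

    name: str
    direction: Direction = Direction.HIGHER_BETTER
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.direction = Direction(self.direction)
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


#: Default feature ranking: prefer dense (bright), structurally varied cells.
DEFAULT_FEATURE_SPECS: List[FeatureSpec] = [
    FeatureSpec("mean", Direction.HIGHER_BETTER, 1.0),
    FeatureSpec("std", Direction.HIGHER_BETTER, 1.0),
    FeatureSpec("entropy", Direction.HIGHER_BETTER, 1.0),
    FeatureSpec("gradient_mean", Direction.HIGHER_BETTER, 1.0),
    FeatureSpec("local_range", Direction.HIGHER_BETTER, 1.0),
]


@dataclasses.dataclass
class GridCell:
    """One grid cell with its pixel bounds and per-cell feature values.

    Bounds are half-open ``[r0, r1) x [c0, c1)`` in image coordinates.
    """

    row: int
    col: int
    bounds: tuple  # (r0, c0, r1, c1)
    features: Dict[str, float]
    score: float = 0.0

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        r0, c0, r1, c1 = self.bounds
        return pixels[r0:r1, c0:c1]


def _entropy(cell: np.ndarray, bins: int = 64) -> float:
    """Shannon entropy (bits) of the cell's intensity histogram."""
    lo, hi = float(cell.min()), float(cell.max())
    if hi - lo < 1e-12:
        return 0.0
    hist, _ = np.histogram(cell, bins=bins, range=(lo, hi))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _cell_features(cell: np.ndarray) -> Dict[str, float]:
    gy, gx = np.gradient(cell)
    return {
        "mean": float(cell.mean()),
        "std": float(cell.std()),
        "entropy": _entropy(cell),
        "gradient_mean": float(np.hypot(gy, gx).mean()),
        "local_range": float(cell.max() - cell.min()),
    }


def compute_grid_features(img: GrayImage, breast: BreastMask, cell_px: int = 200,
                          min_coverage: float = 0.9) -> List[GridCell]:
    """Compute per-cell texture features over the breast region.

    Cells are non-overlapping ``cell_px`` squares anchored at the origin; cells
    with breast coverage below ``min_coverage`` are excluded.
    """
    if cell_px < 16:
        raise ValueError("cell_px must be >= 16")
    h, w = img.shape
    if h < cell_px or w < cell_px:
        raise ValueError("image smaller than one grid cell")
    if breast.mask.shape != img.shape:
        raise ValueError("breast mask must match image shape")
    cells: List[GridCell] = []
    for row in range(h // cell_px):
        for col in range(w // cell_px):
            r0, c0 = row * cell_px, col * cell_px
            r1, c1 = r0 + cell_px, c0 + cell_px
            coverage = breast.mask[r0:r1, c0:c1].mean()
            if coverage < min_coverage:
                continue
            cells.append(GridCell(row=row, col=col, bounds=(r0, c0, r1, c1),
                                  features=_cell_features(img.pixels[r0:r1, c0:c1])))
    if not cells:
        raise ValueError("no grid cell with sufficient breast coverage")
    return cells


def select_insertion_site(cells: Sequence[GridCell],
                          specs: Sequence[FeatureSpec] = None) -> GridCell:
    """Pick the winning cell by direction-aware weighted rank aggregation.

    Each feature contributes its weighted rank (average ranks on ties; the
    best value of a feature receives the largest rank); scores are summed and
    the argmax cell returned. Ties on the aggregate break by (row, col)
    lexicographic order, which also makes the selection invariant to the
    ordering of the input cell list.
    """
    if specs is None:
        specs = DEFAULT_FEATURE_SPECS
    if not cells or not specs:
        raise ValueError("cells and specs must be nonempty")
    scores = np.zeros(len(cells))
    for spec in specs:
        values = np.array([c.features[spec.name] for c in cells], dtype=float)
        if spec.direction is Direction.LOWER_BETTER:
            values = -values
        scores += spec.weight * stats.rankdata(values, method="average")
    for cell, s in zip(cells, scores):
        cell.score = float(s)
    order = sorted(range(len(cells)),
                   key=lambda i: (-scores[i], cells[i].row, cells[i].col))
    return cells[order[0]]
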