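"""Lesion enhancement: measurement, distribution fitting, sampling, insertion.

In the recombined CEM image, lesion enhancement is quantified as the ratio

    e = meanPV_lesion / meanPV_background,

where the background is an equal-area ring obtained by incrementally dilating
the lesion mask: the first dilation stop encloses twice the lesion pixel
count (dilation minus lesion = the *perilesional* ring), the second stop
three times the count (the outermost ring is the *background*). Measured
ratios for real calcified lesions range from 1.00 (no enhancement) up to
about 1.06.

The per-(class, view) probability distribution of measured values is fitted
with a Gaussian kernel on a uniform grid over [1.00, 1.06] and normalized so
the weighted sum of grid probabilities is exactly 1. Simulated lesions draw
their enhancement from this distribution (inverse-CDF sampling with
within-bin jitter), and the value is inserted into the recombined image as a
multiplicative template smoothed with a sigma = 5.0 Gaussian so enhancement
decreases gradually toward the lesion edge.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .cluster_synthesis import LesionClass
from .insertion import LesionMask
from .raster_io import GrayImage, View

ENHANCEMENT_RANGE: Tuple[float, float] = (1.00, 1.06)

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 1-px 8-connected dilation step


class Provenance(str, enum.Enum):
    MEASURED = "measured"
    SAMPLED = "sampled"


@dataclasses.dataclass
class EnhancementValue:
    """A dimensionless enhancement ratio with its provenance."""

    value: float
    provenance: Provenance = Provenance.MEASURED

    def __post_init__(self) -> None:
        if self.value < 1.0:
            raise ValueError("enhancement ratio must be >= 1.0")
        self.provenance = Provenance(self.provenance)


@dataclasses.dataclass
class RingDecomposition:
    """Lesion mask plus its equal-area perilesional and background rings."""

    lesion: np.ndarray
    perilesional: np.ndarray
    background: np.ndarray


@dataclasses.dataclass
class EnhancementDistribution:
    """Discretized enhancement distribution for one (class, view) subset."""

    lesion_class: LesionClass
    view: View
    grid: np.ndarray
    weights: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.lesion_class = LesionClass(self.lesion_class)
        self.view = View(self.view)
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)

    @property
    def subset_key(self) -> Tuple[str, str]:
        return (self.lesion_class.value, self.view.value)

    def is_normalized(self, tol: float = 1e-9) -> bool:
        return abs(float(self.weights.sum()) - 1.0) <= tol

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "lesion_class": self.lesion_class.value, "view": self.view.value,
            "grid": self.grid.tolist(), "weights": self.weights.tolist(),
            "bandwidth": self.bandwidth}))

    @classmethod
    def from_json(cls, path) -> "EnhancementDistribution":
        d = json.loads(Path(path).read_text())
        return cls(lesion_class=d["lesion_class"], view=d["view"],
                   grid=np.array(d["grid"]), weights=np.array(d["weights"]),
                   bandwidth=d["bandwidth"])


# ---------------------------------------------------------------------------
# Ring decomposition
# ---------------------------------------------------------------------------

def build_rings(lesion: LesionMask, image_shape: Tuple[int, int]) -> RingDecomposition:
    """Decompose the surroundings of a lesion into equal-area rings.

    The mask is dilated one 8-connected pixel shell at a time. The first stop
    is the first iteration at which (dilated - lesion) reaches the lesion
    pixel count; the second stop when (dilated - lesion - ring1) reaches it
    again. Ring counts therefore overshoot their targets by at most one
    dilation shell.
    """
    mask = np.asarray(lesion.mask, dtype=bool)
    if mask.shape != tuple(image_shape):
        raise ValueError("lesion mask shape does not match image shape")
    n_lesion = int(mask.sum())
    if n_lesion == 0:
        raise ValueError("empty lesion mask")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("lesion touches the image border; rings undefined")
    if n_lesion * 3 >= mask.size:
        raise ValueError("lesion covers too much of the frame; rings infeasible")

    dilated = mask
    while int(dilated.sum()) - n_lesion < n_lesion:
        grown = ndimage.binary_dilation(dilated, structure=_STRUCT8)
        if grown.sum() == dilated.sum():
            raise ValueError("frame exhausted before perilesional ring complete")
        dilated = grown
    ring1 = dilated & ~mask

    n_r1 = int(ring1.sum())
    while int(dilated.sum()) - n_lesion - n_r1 < n_lesion:
        grown = ndimage.binary_dilation(dilated, structure=_STRUCT8)
        if grown.sum() == dilated.sum():
            raise ValueError("frame exhausted before background ring complete")
        dilated = grown
    ring2 = dilated & ~mask & ~ring1
    return RingDecomposition(lesion=mask, perilesional=ring1, background=ring2)


def measure_enhancement_ratio(recombined: GrayImage,
                              rings: RingDecomposition) -> float:
    """Raw meanPV(lesion) / meanPV(background ring) ratio (may dip below 1)."""
    px = recombined.pixels
    if px.shape != rings.lesion.shape:
        raise ValueError("image and ring shapes differ")
    bg = float(px[rings.background].mean())
    if bg <= 0:
        raise ValueError("background mean must be positive")
    return float(px[rings.lesion].mean()) / bg


def measure_enhancement(recombined: GrayImage,
                        rings: RingDecomposition) -> EnhancementValue:
    """meanPV(lesion) / meanPV(background ring) on the recombined image.

    Ratios marginally below 1 (noise in non-enhancing tissue) clamp to the
    physical floor of 1.0; use :func:`measure_enhancement_ratio` for the raw
    ratio.
    """
    e = measure_enhancement_ratio(recombined, rings)
    return EnhancementValue(value=max(e, 1.0), provenance=Provenance.MEASURED)


# ---------------------------------------------------------------------------
# Distribution fitting and sampling
# ---------------------------------------------------------------------------

def _silverman_bandwidth(values: np.ndarray) -> float:
    n = values.size
    std = values.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(std, iqr / 1.34) if iqr > 0 else std
    h = 0.9 * spread * n ** (-1 / 5)
    # degenerate (all values equal): fall back to one grid-scale kernel width
    return float(h) if h > 0 else 0.002


def fit_enhancement_distribution(values: Sequence[float],
                                 lesion_class, view,
                                 bandwidth: Optional[float] = None,
                                 grid_n: int = 121) -> EnhancementDistribution:
    """Fit the Gaussian-kernel enhancement distribution on [1.00, 1.06].

    The density is a direct Gaussian kernel sum evaluated on a uniform
    ``grid_n``-point grid; weights are renormalized so their sum is exactly 1.
    Bandwidth defaults to Silverman's rule on the input values.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("need at least 2 enhancement values")
    if np.any(vals < 1.0) or np.any(vals > 1.2):
        raise ValueError("enhancement values must lie in [1.0, 1.2]")
    h = float(bandwidth) if bandwidth is not None else _silverman_bandwidth(vals)
    if not h > 0:
        raise ValueError("bandwidth must be positive")
    lo, hi = ENHANCEMENT_RANGE
    grid = np.linspace(lo, hi, grid_n)
    density = np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / h) ** 2).sum(axis=1)
    total = density.sum()
    if total <= 0:
        raise ValueError("degenerate kernel density")
    weights = density / total
    return EnhancementDistribution(lesion_class=lesion_class, view=view,
                                   grid=grid, weights=weights, bandwidth=h)


def sample_enhancement(dist: EnhancementDistribution,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None,
                       size: Optional[int] = None):
    """Draw enhancement value(s) in [1.00, 1.06] by inverse-CDF sampling.

    Grid atoms are drawn from the discrete weights, then jittered uniformly
    within half a grid step and clipped to the distribution's support. Returns
    a single :class:`EnhancementValue` when ``size`` is None, else a list.
    """
    if not dist.is_normalized():
        raise ValueError("distribution weights must sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = 1 if size is None else int(size)
    cdf = np.cumsum(dist.weights)
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    step = dist.grid[1] - dist.grid[0] if dist.grid.size > 1 else 0.0
    vals = dist.grid[idx] + rng.uniform(-0.5, 0.5, n) * step
    lo, hi = ENHANCEMENT_RANGE
    vals = np.clip(vals, lo, hi)
    out = [EnhancementValue(value=float(v), provenance=Provenance.SAMPLED)
           for v in vals]
    return out[0] if size is None else out


# ---------------------------------------------------------------------------
# Enhancement insertion
# ---------------------------------------------------------------------------

def apply_enhancement(recombined: GrayImage, lesion: LesionMask,
                      e: EnhancementValue, smooth_sigma: float = 5.0) -> GrayImage:
    """Insert enhancement into the recombined image inside the lesion mask.

    A template equal to ``e`` inside the mask and 1.0 elsewhere is smoothed
    with a Gaussian kernel (sigma = ``smooth_sigma`` px) so enhancement decays
    gradually toward the lesion edge, then multiplied with the image at the
    cluster location. Pixels beyond the kernel footprint are bit-identical to
    the input (the smoothed excess there is exactly zero).
    """
    if recombined.pixels.shape != lesion.mask.shape:
        raise ValueError("image and lesion mask shapes differ")
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be >= 0")
    excess = np.zeros(recombined.pixels.shape, dtype=np.float64)
    excess[lesion.mask] = e.value - 1.0
    if smooth_sigma > 0:
        excess = ndimage.gaussian_filter(excess, sigma=smooth_sigma,
                                         mode="constant", cval=0.0)
    return recombined.copy_with(recombined.pixels * (1.0 + excess))
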