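"""Synthetic breast-like fixtures: textured CEM image pairs and toy ROI sets.

Clinical CEM data cannot be redistributed, so every downstream stage is
exercised on synthetic fixtures that emulate the statistical structure the
pipeline assumes:

* the *low-energy* fixture is a half-elliptical breast support filled with a
  clustered lumpy background (superposed Gaussian blobs — the standard
  surrogate for mammographic parenchymal texture), overlaid with bright
  caliber-varying curvilinear structures (random-walk chains of Gaussian
  stamps; the Frangi filter responds to these tubular structures, along
  which real calcification clusters tend to form) and Gaussian noise;
* the *recombined* fixture shares the breast support but is smooth and
  low-contrast with no enhancement anywhere, so any measured enhancement
  ratio is ~1.0;
* toy prediction/ground-truth sets plant known error rates (missed lesions,
  spurious predictions, label flips, mask jitter) so evaluation metrics can
  be checked against hand-computed values.

All randomness flows from the single seed in the FixtureSpec; identical
seeds give bit-identical fixtures.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import draw

from .evaluation import (GroundTruthROI, Label2, Label4, LesionType,
                         PredictionROI, binarize_label, lesion_type_of)
from .raster_io import (BreastMask, CaseImagePair, GrayImage, ImageKind,
                        Laterality, View)


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of one synthetic CEM background pair.

    Texture defaults aim for a plausibly mammographic low-energy appearance
    at 0.1 mm pixel pitch: a dense-tissue base with blob clusters of ~0.5 mm
    characteristic length, a handful of bright vessel-like polylines, and
    mild detector noise. Amplitudes are in raw 16-bit-style intensity units.
    """

    shape: Tuple[int, int] = (800, 640)
    spacing_mm: float = 0.1
    view: View = View.CC
    # clustered lumpy texture
    lump_cluster_density: float = 3.0e-4   # blob-cluster centres per px^2
    lumps_per_cluster: int = 12
    cluster_scatter_mm: float = 2.0
    lump_radius_mm: float = 0.5
    lump_amplitude: float = 260.0
    background_level: float = 2400.0       # breast interior base intensity
    outside_level: float = 60.0            # off-breast base intensity
    # curvilinear structures, with round "bead" opacities strung along them
    n_curves: int = 7
    curve_width_mm: float = 0.35
    curve_intensity: float = 520.0
    beads_per_curve: int = 18
    bead_radius_mm: float = 0.25
    # noise
    noise_sigma: float = 28.0
    # recombined image
    recombined_level: float = 1000.0
    recombined_texture_amplitude: float = 4.0
    recombined_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 64:
            raise ValueError("shape too small for a breast half-disc")
        if self.spacing_mm <= 0 or self.noise_sigma < 0:
            raise ValueError("invalid fixture parameters")
        self.view = View(self.view)


def breast_support(shape: Tuple[int, int]) -> np.ndarray:
    """Half-elliptical breast support attached to the left image border."""
    h, w = shape
    cy = (h - 1) / 2.0
    a = 0.46 * h       # vertical semi-axis
    b = 0.82 * w       # horizontal semi-axis
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    return ((rows - cy) / a) ** 2 + (cols / b) ** 2 <= 1.0


def _add_blob(canvas: np.ndarray, cy: float, cx: float, radius_px: float,
              amplitude: float, aspect: float = 1.0, theta: float = 0.0,
              combine: str = "add") -> None:
    """Stamp an elliptical Gaussian blob in a local window.

    ``aspect`` stretches the major axis (sqrt(aspect) * radius) relative to
    the minor (radius / sqrt(aspect)); ``theta`` is the major-axis angle.
    Mild anisotropy mimics the compact oriented opacities of dense tissue,
    to which a vesselness filter responds. ``combine`` is "add" for texture
    superposition or "max" for tube-like envelopes of overlapping stamps.
    """
    major = radius_px * np.sqrt(aspect)
    minor = radius_px / np.sqrt(aspect)
    half = max(int(np.ceil(3 * major)), 2)
    h, w = canvas.shape
    r0, r1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
    c0, c1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1)[:, None] - cy
    xx = np.arange(c0, c1)[None, :] - cx
    u = np.cos(theta) * xx + np.sin(theta) * yy
    v = -np.sin(theta) * xx + np.cos(theta) * yy
    blob = amplitude * np.exp(-(u / major) ** 2 - (v / minor) ** 2)
    if combine == "max":
        np.maximum(canvas[r0:r1, c0:c1], blob, out=canvas[r0:r1, c0:c1])
    else:
        canvas[r0:r1, c0:c1] += blob


def _lumpy_texture(spec: FixtureSpec, support: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Clustered lumpy background: blob clusters scattered over the breast."""
    canvas = np.zeros(spec.shape, dtype=np.float64)
    n_clusters = rng.poisson(spec.lump_cluster_density * support.sum())
    coords = np.argwhere(support)
    if n_clusters == 0 or coords.shape[0] == 0:
        return canvas
    centres = coords[rng.integers(0, coords.shape[0], size=n_clusters)]
    scatter_px = spec.cluster_scatter_mm / spec.spacing_mm
    radius_px = spec.lump_radius_mm / spec.spacing_mm
    for cy, cx in centres:
        for _ in range(spec.lumps_per_cluster):
            oy, ox = rng.normal(0.0, scatter_px, size=2)
            amp = spec.lump_amplitude * rng.uniform(0.5, 1.0)
            rad = radius_px * rng.uniform(0.6, 1.6)
            aspect = rng.uniform(1.5, 3.0)
            theta = rng.uniform(0.0, np.pi)
            _add_blob(canvas, cy + oy, cx + ox, rad, amp, aspect, theta)
    return canvas


def _curvilinear(spec: FixtureSpec, support: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Bright vessel-like structures with varying caliber.

    Each structure is a random-walk chain of overlapping Gaussian profiles
    (combined by maximum, preserving a tubular cross-section) whose radius
    and brightness drift smoothly along the path, with occasional wider
    "bead" bulges. Real ducts and vessels show exactly this caliber
    variation; the bright wide sections give the Frangi x intensity
    candidate mask compact oval regions at the 0.3-1.2 mm scale in addition
    to thin elongated fragments.
    """
    canvas = np.zeros(spec.shape, dtype=np.float64)
    if spec.n_curves == 0:
        return canvas
    h, w = spec.shape
    base_r = max(spec.curve_width_mm / spec.spacing_mm / 2.0, 1.0)
    bead_r = spec.bead_radius_mm / spec.spacing_mm
    for _ in range(spec.n_curves):
        y = rng.uniform(0.15 * h, 0.85 * h)
        x = rng.uniform(0.0, 0.1 * w)
        angle = rng.uniform(-0.5, 0.5)
        radius = base_r * rng.uniform(0.8, 1.3)
        bright = rng.uniform(0.6, 1.0)
        bulge = 0
        n_steps = int(0.45 * w)
        step_of_bead = (np.zeros(n_steps, dtype=bool)
                        if spec.beads_per_curve == 0 else
                        np.isin(np.arange(n_steps),
                                rng.integers(0, n_steps, spec.beads_per_curve)))
        for t in range(n_steps):
            angle += rng.normal(0.0, 0.12)
            angle = float(np.clip(angle, -1.2, 1.2))
            y += 2.0 * np.sin(angle)
            x += 2.0 * np.cos(angle)
            if not (0 <= y < h and 0 <= x < w):
                break
            radius = float(np.clip(radius + rng.normal(0.0, 0.12),
                                   0.6 * base_r, 2.2 * base_r))
            bright = float(np.clip(bright + rng.normal(0.0, 0.14), 0.45, 1.0))
            if step_of_bead[t]:
                bulge = 4                    # bulge persists a few steps
            r_here = max(radius, bead_r) if bulge > 0 else radius
            bulge = max(bulge - 1, 0)
            _add_blob(canvas, y, x, r_here,
                      bright * spec.curve_intensity, combine="max")
    canvas[~support] = 0.0
    return canvas


def generate_background_pair(spec: FixtureSpec) -> CaseImagePair:
    """Generate one deterministic lesion-free low-energy/recombined pair."""
    rng = np.random.default_rng(spec.seed)
    support = breast_support(spec.shape)

    low = np.full(spec.shape, spec.outside_level, dtype=np.float64)
    low[support] = spec.background_level
    low += _lumpy_texture(spec, support, rng) * support
    low += _curvilinear(spec, support, rng)
    if spec.noise_sigma > 0:
        low += rng.normal(0.0, spec.noise_sigma, spec.shape)
    low = np.clip(low, 0.0, None)

    rec = np.full(spec.shape, 0.02 * spec.recombined_level, dtype=np.float64)
    rec[support] = spec.recombined_level
    if spec.recombined_texture_amplitude > 0:
        field = ndimage.gaussian_filter(rng.normal(0.0, 1.0, spec.shape), sigma=40)
        field = field / max(np.abs(field).max(), 1e-12)
        rec += spec.recombined_texture_amplitude * field * support
    if spec.recombined_noise_sigma > 0:
        rec += rng.normal(0.0, spec.recombined_noise_sigma, spec.shape)
    rec = np.clip(rec, 0.0, None)

    low_img = GrayImage(pixels=low, spacing_mm=spec.spacing_mm,
                        view=spec.view, kind=ImageKind.LOW_ENERGY)
    rec_img = GrayImage(pixels=rec, spacing_mm=spec.spacing_mm,
                        view=spec.view, kind=ImageKind.RECOMBINED)
    return CaseImagePair(low_energy=low_img, recombined=rec_img,
                         patient_id=f"fixture-{spec.seed}",
                         laterality=Laterality.L)


def fixture_breast_mask(spec: FixtureSpec) -> BreastMask:
    """Ground-truth breast support of a fixture pair."""
    return BreastMask(mask=breast_support(spec.shape))


def planted_enhancement_values(n: int, seed: int,
                               low: float = 1.0, high: float = 1.06,
                               concentration: Tuple[float, float] = (2.0, 3.0)
                               ) -> np.ndarray:
    """Ground-truth enhancement factors for planted-disc measurement fixtures.

    A Beta(2, 3) draw rescaled to [low, high]: most mass near mild
    enhancement with a tail toward the top of the range, echoing the skew of
    real weakly enhancing calcified lesions.
    """
    rng = np.random.default_rng(seed)
    return low + (high - low) * rng.beta(*concentration, size=n)


# ---------------------------------------------------------------------------
# Toy annotation sets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ErrorRates:
    """Controlled corruption rates for toy prediction sets (all in [0, 1])."""

    drop_rate: float = 0.0        # fraction of GTs with no prediction
    spurious_rate: float = 0.0    # expected spurious predictions per GT
    flip_rate: float = 0.0        # fraction of predictions with flipped class
    max_shift_px: int = 4         # mask jitter, keeps IoU well above 0.1

    def __post_init__(self) -> None:
        for r in (self.drop_rate, self.spurious_rate, self.flip_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclasses.dataclass
class PlantedCounts:
    """True generation log of a toy annotation set."""

    n_gt: int = 0
    n_dropped: int = 0
    n_spurious: int = 0
    n_flipped: int = 0


@dataclasses.dataclass
class ToyAnnotationSet:
    ground_truths: List[GroundTruthROI]
    predictions: List[PredictionROI]
    counts: PlantedCounts
    frame_shape: Tuple[int, int]


_LABEL4_CHOICES = [Label4.BENIGN_MASS, Label4.MALIGNANT_MASS,
                   Label4.BENIGN_CLUSTER, Label4.MALIGNANT_CLUSTER]


def _flip_label(label4: Label4) -> Label4:
    return {Label4.BENIGN_MASS: Label4.MALIGNANT_MASS,
            Label4.MALIGNANT_MASS: Label4.BENIGN_MASS,
            Label4.BENIGN_CLUSTER: Label4.MALIGNANT_CLUSTER,
            Label4.MALIGNANT_CLUSTER: Label4.BENIGN_CLUSTER}[label4]


def _disc_mask(shape, cy, cx, radius) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk((cy, cx), radius, shape=shape)
    mask[rr, cc] = True
    return mask


def generate_toy_annotations(n_patients: int,
                             error_rates: Optional[ErrorRates] = None,
                             seed: int = 0,
                             rois_per_patient: Tuple[int, int] = (1, 3),
                             frame_shape: Tuple[int, int] = (128, 128),
                             roi_radius: int = 10) -> ToyAnnotationSet:
    """Build a toy prediction/ground-truth set with planted error rates.

    Ground truths are discs on a coarse non-overlapping grid (one frame per
    patient and view). Predictions derive from ground truths by jittering the
    disc centre (controlling IoU), dropping GTs (misses), flipping the
    benign/malignant label, and adding spurious non-overlapping discs. The
    returned :class:`PlantedCounts` log holds the true confusion counts.
    """
    if error_rates is None:
        error_rates = ErrorRates()
    rng = np.random.default_rng(seed)
    cell = 4 * roi_radius
    slots_per_dim = (frame_shape[0] // cell, frame_shape[1] // cell)
    n_slots = slots_per_dim[0] * slots_per_dim[1]
    gts: List[GroundTruthROI] = []
    preds: List[PredictionROI] = []
    counts = PlantedCounts()
    for ip in range(n_patients):
        pid = f"toy-{ip:04d}"
        n_rois = int(rng.integers(rois_per_patient[0], rois_per_patient[1] + 1))
        n_spur = rng.binomial(n_rois, error_rates.spurious_rate)
        slots = rng.permutation(n_slots)[: n_rois + n_spur]
        for k, slot in enumerate(slots):
            sy, sx = divmod(int(slot), slots_per_dim[1])
            cy = sy * cell + cell // 2
            cx = sx * cell + cell // 2
            label4 = _LABEL4_CHOICES[rng.integers(0, 4)]
            if k < n_rois:       # a real ground-truth lesion
                counts.n_gt += 1
                gts.append(GroundTruthROI(
                    patient_id=pid, view=View.CC,
                    mask=_disc_mask(frame_shape, cy, cx, roi_radius),
                    label2=binarize_label(label4),
                    lesion_type=lesion_type_of(label4)))
                if rng.random() < error_rates.drop_rate:
                    counts.n_dropped += 1
                    continue
                pred_label = label4
                if rng.random() < error_rates.flip_rate:
                    pred_label = _flip_label(label4)
                    counts.n_flipped += 1
                shift = rng.integers(-error_rates.max_shift_px,
                                     error_rates.max_shift_px + 1, size=2)
                preds.append(PredictionROI(
                    patient_id=pid, view=View.CC,
                    mask=_disc_mask(frame_shape, cy + int(shift[0]),
                                    cx + int(shift[1]), roi_radius),
                    label4=pred_label,
                    pred_score=float(rng.uniform(0.5, 1.0))))
            else:                # a spurious prediction in a free slot
                counts.n_spurious += 1
                preds.append(PredictionROI(
                    patient_id=pid, view=View.CC,
                    mask=_disc_mask(frame_shape, cy, cx, roi_radius),
                    label4=label4,
                    pred_score=float(rng.uniform(0.5, 1.0))))
    return ToyAnnotationSet(ground_truths=gts, predictions=preds,
                            counts=counts, frame_shape=frame_shape)
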