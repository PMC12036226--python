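"""End-to-end orchestration of synthetic CEM case generation.

``simulate_case`` runs the full chain on one lesion-free view pair:
breast segmentation -> grid-based site selection -> Frangi x threshold
candidate extraction -> class-specific filtering -> cluster growth ->
multiplicative template build/degrade/insert (low-energy) -> automatic
lesion-mask generation -> enhancement sampling for the (class, view) subset
-> smoothed multiplicative enhancement (recombined). Views for which too few
candidate regions satisfy the class criteria are reported infeasible and
skipped; both views of one breast always receive the same lesion class.

A single master seed fans out to per-stage random streams through
``numpy.random.SeedSequence`` spawning, so one stage's draw count never
perturbs another stage.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cluster_synthesis as cs
from . import enhancement as enh
from . import insertion as ins
from . import raster_io as rio
from . import site_selection as ss
from .config import SimulationConfig

logger = logging.getLogger("cemsim")


@dataclasses.dataclass
class SimulatedCase:
    """Outputs and provenance of one simulated view."""

    low_energy: rio.GrayImage
    recombined: rio.GrayImage
    lesion_mask: ins.LesionMask
    cluster: cs.ClusterModel
    template: ins.InsertionTemplate
    enhancement_value: enh.EnhancementValue
    provenance: Dict


def _stage_rngs(seed: int) -> Dict[str, np.random.Generator]:
    names = ("cluster", "enhancement")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_case(pair: rio.CaseImagePair, lesion_class,
                  dist: enh.EnhancementDistribution,
                  config: Optional[SimulationConfig] = None,
                  seed: int = 0) -> SimulatedCase:
    """Simulate one microcalcification cluster + enhancement in a view pair.

    ``dist`` must be the fitted enhancement distribution for
    (``lesion_class``, ``pair.view``). Raises
    :class:`~cemsim.cluster_synthesis.InfeasibleClusterError` when the view
    cannot host a cluster of the requested class.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    lesion_class = cs.LesionClass(lesion_class)
    view = pair.low_energy.view
    if (dist.lesion_class, dist.view) != (lesion_class, view):
        raise ValueError("enhancement distribution subset does not match "
                         f"({lesion_class.value}, {view.value})")
    rngs = _stage_rngs(seed)

    breast = rio.segment_breast(pair.low_energy)
    cells = ss.compute_grid_features(pair.low_energy, breast,
                                     cell_px=config.cell_px,
                                     min_coverage=config.min_cell_coverage)
    site = ss.select_insertion_site(cells)
    cell = site.extract(pair.low_energy.pixels)

    mask = cs.candidate_mask(cell, frangi_sigmas=config.frangi_sigmas,
                             frangi_percentile=config.frangi_percentile,
                             intensity_nstd=config.intensity_nstd)
    regions = cs.extract_candidates(mask, pair.low_energy.spacing_mm)
    cs.attach_intensities(regions, cell)
    criteria = cs.ClassCriteria.for_class(lesion_class)
    kept = cs.filter_candidates(regions, criteria)
    cluster = cs.grow_cluster(cell, kept, criteria, site,
                              image_shape=pair.low_energy.shape,
                              subcell_px=config.subcell_px,
                              rng=rngs["cluster"])

    template = ins.build_template(cluster, amplitude=config.template_amplitude)
    template = ins.degrade_template(template, psf_sigma_px=config.psf_sigma_px,
                                    scatter_fraction=config.scatter_fraction)
    low_inserted = ins.insert_template(pair.low_energy, template)
    lesion_mask = ins.generate_lesion_mask(
        cluster.support, expand_iterations=config.expand_iterations,
        offset_px=config.offset_px, dilation_px=config.dilation_px)

    e = enh.sample_enhancement(dist, rng=rngs["enhancement"])
    rec_enhanced = enh.apply_enhancement(
        pair.recombined, lesion_mask, e,
        smooth_sigma=config.enhancement_smooth_sigma)

    provenance = {
        "patient_id": pair.patient_id,
        "view": view.value,
        "laterality": pair.laterality.value,
        "lesion_class": lesion_class.value,
        "seed": seed,
        "anchor_cell": {"row": site.row, "col": site.col,
                        "bounds": list(site.bounds)},
        "calcification_count": cluster.count,
        "enhancement_value": e.value,
        "config": dataclasses.asdict(config),
    }
    return SimulatedCase(low_energy=low_inserted, recombined=rec_enhanced,
                         lesion_mask=lesion_mask, cluster=cluster,
                         template=template, enhancement_value=e,
                         provenance=provenance)


def simulate_breast(pairs: Sequence[rio.CaseImagePair], lesion_class,
                    dists: Dict[Tuple[str, str], enh.EnhancementDistribution],
                    config: Optional[SimulationConfig] = None,
                    seed: int = 0) -> List[Optional[SimulatedCase]]:
    """Simulate all views of one breast with a shared lesion class.

    The cluster models of CC and MLO views differ (each is grown from its own
    image) but the class is forced to be the same. Infeasible views yield
    None, with the skip reason logged.
    """
    lesion_class = cs.LesionClass(lesion_class)
    results: List[Optional[SimulatedCase]] = []
    for i, pair in enumerate(pairs):
        key = (lesion_class.value, pair.low_energy.view.value)
        try:
            results.append(simulate_case(pair, lesion_class, dists[key],
                                         config=config, seed=seed + i))
        except cs.InfeasibleClusterError as exc:
            logger.info("skipping %s %s view: %s", pair.patient_id,
                        pair.low_energy.view.value, exc)
            results.append(None)
    return results


# ---------------------------------------------------------------------------
# Dataset composition
# ---------------------------------------------------------------------------

def compose_dataset(real_records: pd.DataFrame,
                    synthetic_records: pd.DataFrame,
                    real_fraction: float = 1.0,
                    synth_multiple: float = 0.0,
                    seed: int = 0) -> pd.DataFrame:
    """Compose a training manifest from real and synthetic record pools.

    Records need columns ``patient_id``, ``label`` (benign/malignant) and
    ``lesion_type`` (mass/cluster). Real patients are sampled at
    ``real_fraction`` per (label, lesion_type) stratum, preserving the
    benign:malignant and mass:cluster ratios; the synthetic set is sized as
    ``synth_multiple`` times the number of real *cluster* records in the full
    pool, preserving the real pool's benign:malignant cluster ratio.
    """
    if not 0.0 < real_fraction <= 1.0:
        raise ValueError("real_fraction must lie in (0, 1]")
    if synth_multiple < 0:
        raise ValueError("synth_multiple must be >= 0")
    rng = np.random.default_rng(seed)

    chosen_parts = []
    for _, stratum in real_records.groupby(["label", "lesion_type"], sort=True):
        patients = np.array(sorted(stratum["patient_id"].unique()))
        n_take = int(round(real_fraction * len(patients)))
        if real_fraction == 1.0:
            n_take = len(patients)
        take = rng.choice(patients, size=n_take, replace=False)
        chosen_parts.append(stratum[stratum["patient_id"].isin(take)])
    real_out = (pd.concat(chosen_parts) if chosen_parts
                else real_records.iloc[:0]).assign(source="real")

    cluster_pool = real_records[real_records["lesion_type"] == "cluster"]
    n_target = int(round(synth_multiple * len(cluster_pool)))
    synth_parts = []
    if n_target > 0:
        if len(synthetic_records) < n_target:
            raise ValueError("requested synthetic size exceeds the pool")
        labels = sorted(cluster_pool["label"].unique())
        ratios = {lab: (cluster_pool["label"] == lab).mean() for lab in labels}
        remaining = n_target
        for k, lab in enumerate(labels):
            n_lab = (remaining if k == len(labels) - 1
                     else int(round(n_target * ratios[lab])))
            pool = synthetic_records[synthetic_records["label"] == lab]
            if len(pool) < n_lab:
                raise ValueError(
                    f"requested synthetic size exceeds the pool for {lab!r}")
            idx = rng.choice(pool.index.to_numpy(), size=n_lab, replace=False)
            synth_parts.append(pool.loc[np.sort(idx)])
            remaining -= n_lab
    synth_out = (pd.concat(synth_parts) if synth_parts
                 else synthetic_records.iloc[:0]).assign(source="synthetic")

    return pd.concat([real_out, synth_out], ignore_index=True)


def split_patients(records: pd.DataFrame, fractions: Sequence[float],
                   seed: int = 0) -> List[pd.DataFrame]:
    """Split a record pool into disjoint patient-level subsets."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    patients = np.array(sorted(records["patient_id"].unique()))
    rng.shuffle(patients)
    out = []
    start = 0
    for k, f in enumerate(fractions):
        stop = len(patients) if k == len(fractions) - 1 \
            else start + int(round(f * len(patients)))
        chunk = set(patients[start:stop])
        out.append(records[records["patient_id"].isin(chunk)])
        start = stop
    return out
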