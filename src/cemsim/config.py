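"""Run configuration: every tunable parameter of the simulation pipeline.

The resolved configuration is written beside every run's outputs so each
artifact is reproducible from its provenance record (config + seeds).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class SimulationConfig:
    # geometry
    spacing_mm: float = 0.1          # GE CEM systems are close to this pitch
    # site selection
    cell_px: int = 200
    min_cell_coverage: float = 0.9
    # candidate extraction
    frangi_sigmas: tuple = (2.0, 4.0, 6.0)
    frangi_percentile: float = 90.0
    intensity_nstd: float = 1.0
    subcell_px: int = 10
    # insertion template
    template_amplitude: float = 0.15
    psf_sigma_px: float = 1.0
    scatter_fraction: float = 0.2
    # automatic mask generation
    expand_iterations: int = 2
    offset_px: float = 2.0
    dilation_px: int = 5
    # enhancement
    kde_grid_n: int = 121
    enhancement_smooth_sigma: float = 5.0
    # CLAHE preprocessing
    clahe_tiles: int = 8
    clahe_clip_limit: float = 0.01
    # evaluation
    iou_threshold: float = 0.1
    score_threshold: float = 0.1
    class_prob_threshold: float = 0.5
    n_bootstrap: int = 2000
    # dataset composition
    real_fraction: float = 1.0
    synth_multiple: float = 0.0

    def validate(self) -> "SimulationConfig":
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.cell_px < 16 or self.cell_px % self.subcell_px:
            raise ValueError("cell_px must be >= 16 and divisible by subcell_px")
        if not 0 < self.min_cell_coverage <= 1:
            raise ValueError("min_cell_coverage must lie in (0, 1]")
        if self.template_amplitude <= 0:
            raise ValueError("template_amplitude must be positive")
        if not 0 <= self.scatter_fraction < 1:
            raise ValueError("scatter_fraction must lie in [0, 1)")
        if not 0 < self.real_fraction <= 1:
            raise ValueError("real_fraction must lie in (0, 1]")
        if self.synth_multiple < 0:
            raise ValueError("synth_multiple must be >= 0")
        return self

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["frangi_sigmas"] = list(self.frangi_sigmas)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "frangi_sigmas" in data:
            data["frangi_sigmas"] = tuple(data["frangi_sigmas"])
        return cls(**data).validate()
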