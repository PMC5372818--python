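"""Flat JSON pipeline configuration with documented keys.

Every tunable of the reconstruction lives here with its module default;
``load(save(c)) == c`` round-trips exactly, and there are no hidden defaults
outside this class.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # image
    background_label: int = 1
    voxel_size: Optional[Tuple[float, float, float]] = None  # metadata wins

    # adjacency-complex optimization
    draco_w_image: float = 1.0
    draco_w_prior: float = 0.1
    draco_w_regularity: float = 0.1
    neighbor_target: float = 13.2
    max_edge_factor: float = 3.0
    sliver_min_dihedral_deg: float = 5.0
    sliver_radius_edge: float = 4.0
    draco_t_start: float = 1.0
    draco_t_end: float = 0.01
    draco_cycles: int = 3
    draco_cooling: float = 0.95
    constrain_margin: float = 0.05
    layers: Optional[str] = None  # None, "L1L2", or "L1"

    # mesh enhancement
    split_rounds: int = 1
    remesh_target: Optional[float] = None  # edge length in μm; None = skip
    project_surface: bool = True
    pin_corners: bool = True
    run_stem: bool = True
    stem_w_image: float = 1.0
    stem_w_prior: float = 0.5
    stem_w_regularity: float = 0.5
    shift_radius: Optional[float] = None  # None = half the median edge
    stem_t_start: float = 1e-4
    stem_t_end: float = 5e-6
    stem_cycles: int = 2
    stem_cooling: float = 0.7

    # quality normalizers
    d0: float = 0.25 * 3 ** 0.5  # corner-distance reference (μm)
    complexity_reference: float = 152.0
    angle_reference_deg: float = 30.0

    # reproducibility
    rng_seed: int = 0

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        if cfg.voxel_size is not None:
            cfg.voxel_size = tuple(cfg.voxel_size)
        return cfg
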