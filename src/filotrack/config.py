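"""Pipeline configuration: one dataclass, one YAML file, all stages.

Every tunable parameter of the pipeline lives here with its declared
default (matching the per-module defaults), round-trips losslessly through
YAML, and can be overridden from the command line (CLI flags take
precedence over the config file, which takes precedence over defaults).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # geometry
    voxel_size: tuple[float, float, float] = (0.3, 0.25, 0.25)
    pixel_size: float = 0.5  # 2-D cluster images, µm

    # segmentation
    threshold_method: str = "otsu"
    local_threshold_method: str = "otsu"
    min_object_voxels: int = 27
    min_peak_separation: float = 5.0   # µm, watershed seed separation
    fragment_threshold: float = 10.0   # µm, equivalent-diameter exclusion
    elongation_threshold: float = 1.5  # polarity axis ratio
    opening_radius: float = 1.0        # µm, main-body opening

    # filopodia
    sigma_small: float = 0.3           # µm, DoG inner scale
    sigma_large: float = 1.0           # µm, DoG outer scale
    prune_length: float = 1.0          # µm, skeleton spur pruning
    closing_radius: float = 0.3        # µm, filament-mask closing
    membrane_shell: float = 1.0        # µm, base attachment shell

    # clusters
    cluster_adjacency: float = 2.0     # µm
    cluster_cell_diameter: float = 10.0  # µm (min area = 3 profiles)
    cluster_min_area: float | None = None  # µm², overrides the 3-profile rule

    # tracks
    track_pixel_size: float = 1.0      # µm per unit in track tables

    # statistics
    alpha: float = 0.05
    gate_alpha: float = 0.05

    # synthetic-data / reproducibility
    seed: int = 0

    # paths
    input_dir: str = "."
    output_dir: str = "filotrack_out"

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "voxel_size" in d:
            d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Hash of the analysis parameters; file locations are excluded so
        the same analysis run into different directories hashes equal."""
        d = self.to_dict()
        d.pop("input_dir", None)
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
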