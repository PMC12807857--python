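"""Run configuration: one flat YAML document driving every pipeline stage.

Every run writes its fully resolved configuration next to its outputs so a
run can always be reproduced from the artifact directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .proteomics import RulerConfig
from .segmentation import SegmentationConfig
from .synthetic import IntensityModel, NoiseModel, SceneParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of an end-to-end run on a synthetic population."""

    seed: int = 0
    n_lo_cells: int = 2
    n_hi_cells: int = 2
    scene: SceneParams = field(default_factory=SceneParams)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    ruler: RulerConfig = field(default_factory=RulerConfig)
    asymmetry_threshold: float = 0.2
    strata_intensity_column: str = "mean_snaptag"
    embed: bool = False  # UMAP embedding is slow; opt-in for pipelines
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        nested = {
            "scene": SceneParams,
            "intensity_model": IntensityModel,
            "segmentation": SegmentationConfig,
            "ruler": RulerConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in nested and isinstance(value, dict):
                value = dict(value)
                if key == "scene" and isinstance(value.get("noise"), dict):
                    value["noise"] = NoiseModel(**value["noise"])
                for tup in ("tubule_length_um", "psf_sigma_um", "spacing_um",
                            "cell_radii_um", "hi_counts", "fusion_channels"):
                    if isinstance(value.get(tup), list):
                        value[tup] = tuple(value[tup])
                if isinstance(value.get("morph_ops"), list):
                    value["morph_ops"] = tuple(
                        tuple(op) for op in value["morph_ops"]
                    )
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
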