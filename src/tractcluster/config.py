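"""Pipeline configuration: one YAML-serializable object drives every stage.

The config round-trips losslessly through YAML, and its hash is recorded
in every output manifest so artifacts can be traced to the exact settings
that produced them.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .atlas import ToyAtlasSpec
from .levels import LevelScheme
from .registration import RegistrationConfig
from .signatures import METRICS


@dataclass
class PipelineConfig:
    """All knobs of the parcellation pipeline, with study-scale defaults.

    Defaults mirror the study conditions: 5 subjects, the full 31-level
    scheme, pixel noise at the signature spread (noise_scale 1), and a
    small smooth inter-subject deformation.
    """

    out_dir: str = "pipeline_out"
    master_seed: int = 0
    # generator
    n_subjects: int = 5
    grid_shape: tuple[int, int] = (64, 64)
    noise_scale: float = 1.0
    deform_amplitude: float = 1.5
    merge_lf_vf: bool = True
    level_counts: dict[str, int] = field(
        default_factory=lambda: {"cervical": 8, "thoracic": 13, "lumbar": 6, "sacral": 4}
    )
    # registration
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    # clustering
    mode: str = "slice"            # slice | region
    n_clusters: int = 8
    sweep: tuple[int, int] | None = None
    connectivity: str = "axial4"
    metrics: tuple[str, ...] = METRICS
    # evaluation
    render: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("slice", "region"):
            raise ValueError(f"unknown clustering mode {self.mode!r}")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")

    # -- derived objects ---------------------------------------------------
    def scheme(self) -> LevelScheme:
        return LevelScheme(counts=dict(self.level_counts))

    def atlas_spec(self) -> ToyAtlasSpec:
        return ToyAtlasSpec(shape=tuple(self.grid_shape), merge_lf_vf=self.merge_lf_vf)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["metrics"] = list(self.metrics)
        d["sweep"] = list(self.sweep) if self.sweep else None
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        if "registration" in d and isinstance(d["registration"], dict):
            d["registration"] = RegistrationConfig(**d["registration"])
        for key in ("grid_shape", "metrics", "sweep"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
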