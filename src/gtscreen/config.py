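"""Run configuration: one serialisable record drives every workflow.

A RunConfig can round-trip through YAML/JSON; each report embeds the exact
configuration used plus its hash, so two runs with the same hash produce
identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from gtscreen.simulate.params import GrowthParams, ImageParams


@dataclass
class PlateConfig:
    n_compounds: int = 438
    compounds_per_plate: int = 80
    replicates: int = 4
    controls_per_plate: int = 32
    plate_format: int = 384


@dataclass
class EffectConfig:
    """Planted compound-effect truth for the synthetic screen."""

    n_hypo: int = 60
    effect_hypo: float = 0.3
    n_hyper: int = 20
    effect_hyper: float = 1.8
    shrinkage_fraction: float = 0.5
    shrinkage_shift: float = -40.0


@dataclass
class SegmentationConfig:
    min_area: float = 20.0
    max_area: float = 5000.0
    threshold_method: str = "otsu"
    split_touching: bool = True
    min_separation: float = 6.0
    background_subtract: bool = True


@dataclass
class SirnaConfig:
    """Gene-silencing assay: per-gene per-sex growth-rate factors and the
    planted knockdown fold confirmed by qPCR."""

    genes: dict = field(
        default_factory=lambda: {
            "Ar": {"male": 0.85, "female": 1.0},
            "Gli3": {"male": 0.87, "female": 1.0},
            "Mafb": {"male": 0.92, "female": 0.93},
        }
    )
    knockdown_fold: float = 0.2
    timepoints: tuple = (1.0, 3.0, 6.0)
    replicates: int = 4
    qpcr_noise_sd: float = 0.1


@dataclass
class RunConfig:
    seed: int = 0
    workflow: str = "screen"
    out_dir: str = "gtscreen_out"
    from_counts: bool = True
    days: float = 6.0
    k: float = 3.0
    size_k: float = 3.0
    inclusive: bool = True
    include_controls_in_stats: bool = True
    pixel_scale_um2: float | None = None  # optional area calibration, um^2/pixel^2
    plate: PlateConfig = field(default_factory=PlateConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    growth: GrowthParams = field(default_factory=GrowthParams)
    imaging: ImageParams = field(default_factory=ImageParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    sirna: SirnaConfig = field(default_factory=SirnaConfig)

    def validate(self) -> None:
        if self.k <= 0 or self.size_k <= 0:
            raise ValueError("MAD multipliers k and size_k must be positive")
        if self.days < 0:
            raise ValueError("days must be non-negative")
        if self.workflow not in ("screen", "sirna"):
            raise ValueError(f"unknown workflow: {self.workflow!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sirna"]["timepoints"] = list(self.sirna.timepoints)
        d["growth"]["modulators"] = {
            k: dict(v) for k, v in self.growth.modulators.items()
        }
        return d

    def hash(self) -> str:
        """Hash of the numerically relevant configuration (output paths
        excluded): equal hashes imply identical numeric outputs."""
        d = self.to_dict()
        d.pop("out_dir", None)
        canonical = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        nested = {
            "plate": PlateConfig,
            "effects": EffectConfig,
            "growth": GrowthParams,
            "imaging": ImageParams,
            "segmentation": SegmentationConfig,
            "sirna": SirnaConfig,
        }
        kwargs = {}
        for key, value in d.items():
            if key in nested and isinstance(value, dict):
                value = dict(value)
                if key == "imaging" and "field_shape" in value:
                    value["field_shape"] = tuple(value["field_shape"])
                if key == "growth" and "n0_range" in value:
                    value["n0_range"] = tuple(value["n0_range"])
                if key == "sirna" and "timepoints" in value:
                    value["timepoints"] = tuple(value["timepoints"])
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2, default=str))
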