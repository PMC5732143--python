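"""Run configuration with documented defaults and YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import AcquisitionGeometry
from .segmentation import SegmentationOptions


@dataclass
class SimulateConfig:
    """Synthetic-plate settings used when no instrument images exist."""

    cell_line: str = "VCaP"
    seeded_cells: int = 2000
    drug: str = "MLN4924"
    concentrations: list = field(default_factory=lambda: [0, 10, 30, 100, 300])
    model: str = "arrest"
    ec50s: list = field(default_factory=lambda: [50.0])
    hill: float = 1.0
    replicates: int = 3
    timepoints: list = field(default_factory=lambda: [0.0, 2.0, 4.0])
    growth_rate: float = 0.10
    noise_sd: float = 200.0


@dataclass
class FitConfig:
    kind: str = "auto"  # 'monophasic' | 'biphasic' | 'auto'
    n_starts: int = 8
    seed: int = 0


@dataclass
class RunConfig:
    out_dir: str = "spherohca_out"
    seed: int = 0
    design_csv: str | None = None
    images_dir: str | None = None
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    segmentation: SegmentationOptions = field(default_factory=SegmentationOptions)
    #: per-cell-line minimum object area in px^2 (debris rejection)
    min_area_px2: dict = field(
        default_factory=lambda: {"VCaP": 1000, "LNCaP": 3000, "default": 1000}
    )
    morphometry_mode: str = "largest"  # or 'union' for disrupted spheroids
    fit: FitConfig = field(default_factory=FitConfig)
    threshold_alpha: float = 0.05

    def min_area_for(self, cell_line: str) -> int:
        return int(self.min_area_px2.get(cell_line, self.min_area_px2["default"]))

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if kw.get("simulate") is not None:
            kw["simulate"] = SimulateConfig(**kw["simulate"])
        if "geometry" in kw:
            kw["geometry"] = AcquisitionGeometry(**kw["geometry"])
        if "segmentation" in kw:
            kw["segmentation"] = SegmentationOptions(**kw["segmentation"])
        if "fit" in kw:
            kw["fit"] = FitConfig(**kw["fit"])
        return cls(**kw)
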