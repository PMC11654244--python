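"""Run configuration: stage parameters, YAML round-trip, provenance hash.

Defaults follow the screen's published conventions where one exists: growth
thresholds 0.5 (permissive) and 0.1 (stringent), colony presence over 50
A.U., two-SD cell trimming and autofluorescence band, 65x65 crops on a
20x20 grid with 0.35% pixel saturation.  (The 5 uM inducer concentration is
wet-lab metadata and is carried for provenance only.)
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "GrowthParams",
    "FluorParams",
    "KineticsParams",
    "MontageParams",
    "SimParams",
    "RunConfig",
]


@dataclass
class GrowthParams:
    permissive: float = 0.5
    stringent: float = 0.1
    presence_threshold: float = 50.0
    trim_k: float = 2.0


@dataclass
class FluorParams:
    alpha: float = 0.05
    min_effect: float = 0.75
    death_fraction: float = 0.25
    trim_k: float = 2.0


@dataclass
class KineticsParams:
    min_amplitude: float = 0.1
    bootstrap_draws: int = 1000


@dataclass
class MontageParams:
    box_size: int = 65
    grid_rows: int = 20
    grid_cols: int = 20
    saturate_fraction: float = 0.0035


@dataclass
class SimParams:
    """Synthetic-screen scale for the end-to-end pipeline demo."""

    n_strains: int = 384
    layout_rows: int = 16
    layout_cols: int = 24
    lethal_fraction: float = 0.1
    effect_size: float = 0.05
    noise_cv: float = 0.1
    edge_boost: float = 1.2
    n_cells: int = 200
    depletion_factor: float = 0.3
    t50_min: float = 45.0
    plateau: float = 0.1
    tc_noise_cv: float = 0.05
    n_montage_cells: int = 40
    inducer_um: float = 5.0  # metadata only


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "degronscreen_run"
    stages: list[str] = field(
        default_factory=lambda: ["growth", "fluor", "kinetics", "goslim", "group", "montage"]
    )
    growth: GrowthParams = field(default_factory=GrowthParams)
    fluor: FluorParams = field(default_factory=FluorParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    montage: MontageParams = field(default_factory=MontageParams)
    sim: SimParams = field(default_factory=SimParams)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the analysis parameters; stamped on every output.

        Output paths are excluded: two runs of the same analysis into
        different directories are the same run.
        """
        d = self.to_dict()
        d.pop("outdir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for name, sub in (
            ("growth", GrowthParams),
            ("fluor", FluorParams),
            ("kinetics", KineticsParams),
            ("montage", MontageParams),
            ("sim", SimParams),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)
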