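"""Pipeline configuration: every stage parameter with its study default.

``PipelineConfig`` gathers the tunables of all stages — association
thresholds, stoichiometry windows and fluorescent probability, motility
thresholds, hotspot DBSCAN parameters, simulation sizes — under a single
master seed, and round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dynamics import MotilityThresholds
from .hotspots import HotspotParams

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # master seed for every simulated stage
    seed: int = 0

    # nearest-neighbor association
    nn_threshold_nm: float = 100.0
    nn_tight_threshold_nm: float = 50.0

    # stoichiometry
    p_fluor: float = 0.8
    early_window: tuple[int, int] = (0, 30)    # frames 1-30 (0-based half-open)
    late_window: tuple[int, int] = (600, 700)
    step_sensitivity: float = 2.0

    # motility
    d_immobile: float = 0.01       # µm²/s
    confined_max: float = 0.1
    anomalous_max: float = 0.9
    brownian_max: float = 1.1
    n_points_d: int = 4
    alpha_fit_fraction: float = 0.5
    frame_interval: float = 0.05   # s

    # hotspots (sptPALM mode)
    hotspot_eps_nm: float = 80.0
    hotspot_min_density: int = 20
    hotspot_min_locs: int = 18

    # projection rendering
    projection_pixel_nm: float = 100.0
    projection_psf_sigma_nm: float = 200.0 / 2.35
    projection_threshold_quantile: float = 0.99

    # simulation sizes
    sim_n_tracks: int = 1000
    sim_n_frames: int = 50
    sim_localization_error_nm: float = 16.0
    sim_spot_density: float = 10.0   # per µm²
    sim_dark_fraction: float = 0.2

    # paths
    output_dir: str = "smlmkit_output"

    def motility_thresholds(self) -> MotilityThresholds:
        return MotilityThresholds(
            d_immobile=self.d_immobile,
            confined_max=self.confined_max,
            anomalous_max=self.anomalous_max,
            brownian_max=self.brownian_max,
        )

    def hotspot_params(self) -> HotspotParams:
        return HotspotParams(
            eps=self.hotspot_eps_nm,
            min_density=self.hotspot_min_density,
            min_locs_per_hotspot=self.hotspot_min_locs,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["early_window"] = list(self.early_window)
        d["late_window"] = list(self.late_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("early_window", "late_window"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
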