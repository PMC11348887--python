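"""Pipeline configuration.

All tunable constants of the assay live here, grouped by stage.  Defaults are
the values used throughout: IEG positivity thresholds of 800 AFU (FOS) and
1,000 AFU (EGR-1), viability exclusion at z < -2, PCA hit calling at PC1 > 4,
top-5 single-parameter rescue, a 9-s.d. extracellular spike threshold, a
1 spike/s network-burst threshold, the top-1/64 electrode summary, and the
5-s / 20-min calcium acquisition schedule.

Configs are plain dataclasses that round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ThresholdConfig",
    "ScreenConfig",
    "ActivityConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass
class ThresholdConfig:
    """Image-analysis thresholds and geometry parameters.

    fos_afu / egr1_afu
        Nuclear mean-intensity cutoffs for IEG positivity; positivity is
        strict (``> threshold``), so a nucleus exactly at the cutoff is
        negative.
    dapi_min_area / dapi_max_area
        Intact-nucleus area gate in μm²; regions outside are discarded.
    map2_threshold_method
        Global thresholding method for the neurite channel (``otsu`` or a
        fixed AFU value as a string number).
    puncta_min_sigma / puncta_max_sigma
        Laplacian-of-Gaussian blob scales, in px.
    apposition_radius
        Max SYN1-PSD95 centroid distance (μm) for a punctum to count as
        apposed.
    neurite_mask_dilation
        Dilation (μm) of the MAP2-positive mask when restricting puncta
        detection to the area surrounding neurites.
    """

    fos_afu: float = 800.0
    egr1_afu: float = 1000.0
    dapi_min_area: float = 30.0
    dapi_max_area: float = 500.0
    map2_threshold_method: str = "otsu"
    puncta_min_sigma: float = 1.0
    puncta_max_sigma: float = 3.0
    apposition_radius: float = 1.0
    neurite_mask_dilation: float = 2.0

    def __post_init__(self) -> None:
        if self.fos_afu <= 0 or self.egr1_afu <= 0:
            raise ValueError("IEG AFU thresholds must be positive")
        if not self.dapi_min_area < self.dapi_max_area:
            raise ValueError("dapi_min_area must be < dapi_max_area")


@dataclass
class ScreenConfig:
    """Hit-selection parameters for the compound screen."""

    viability_z: float = -2.0
    pc1_threshold: float = 4.0
    top_k: int = 5
    doses_nm: tuple = (30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0)
    bscore_max_iter: int = 100
    bscore_tol: float = 1e-6
    robust_z: bool = True  # median/MAD; False -> mean/SD
    bscore_per_parameter: bool = True

    def __post_init__(self) -> None:
        self.doses_nm = tuple(float(d) for d in self.doses_nm)


@dataclass
class ActivityConfig:
    """Spike, burst and calcium-event detection parameters."""

    spike_threshold_sd: float = 9.0
    spike_refractory_s: float = 0.002
    burst_rate_threshold: float = 1.0  # spikes/s per channel, array-wide
    burst_bin_s: float = 0.1
    burst_merge_gap_s: float = 0.2
    burst_rate_mode: str = "per_channel"  # or "total"
    top_fraction: float = 1.0 / 64.0
    rate_window_s: float = 60.0
    calcium_frame_interval_s: float = 5.0
    calcium_duration_s: float = 1200.0
    calcium_event_sd: float = 3.0
    dff_baseline_percentile: float = 10.0
    dff_window_frames: int = 60


@dataclass
class PipelineConfig:
    """Top-level configuration: one seed, one output directory, all stages."""

    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    preset: str = "hpsc_day21"
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("thresholds", ThresholdConfig),
            ("screen", ScreenConfig),
            ("activity", ActivityConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg.to_dict()), fh, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples to lists so YAML stays tag-free."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_hash(cfg: PipelineConfig) -> str:
    """Stable content hash of a configuration (sha256 of canonical JSON)."""
    blob = json.dumps(_plain(cfg.to_dict()), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
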