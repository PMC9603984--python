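"""Flat, validated pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    """Every stage parameter of an end-to-end run, in one flat record.

    Defaults follow the primary-screen acquisition and analysis settings:
    13 frames at 15-min intervals, inclusion at >= 8 of 13 frames, slope-SE
    cutoff 2.5, plate normalization by compound-well median/IQR with linear
    (type-7) quantiles, and a hit threshold of 1.0 normalized units.
    """

    version: int = CONFIG_VERSION
    seed: int = 0
    # inputs: empty detections_csv means "simulate"
    detections_csv: str = ""
    layout_csv: str = ""
    out_dir: str = "run"
    # simulation (used when detections_csv is empty)
    n_plates: int = 4
    n_compound_wells: int = 160
    n_dmso: int = 8
    n_eact: int = 8
    n_actives: int = 10
    active_effect_iqr: float = 3.0
    # detection / areas
    diameter_rule: str = "mean"
    # tracking
    max_displacement: float = 30.0
    memory: int = 5
    # swell kinetics QC
    n_frames: int = 13
    min_frames_frac: float = 8.0 / 13.0
    se_max: float = 2.5
    # screen statistics
    hit_threshold: float = 1.0
    quantile_method: str = "linear"
    exclude_controls: bool = True
    # fluorescence AUC
    auc_t_end: float = 120.0
    # trace analysis
    isc_n_points: int = 5
    quench_window: int = 5

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config key(s): {sorted(unknown)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False)
        )
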