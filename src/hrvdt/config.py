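"""Pipeline configuration: every tunable the stages expose, with defaults.

A fully-defaulted config reproduces the reference end-to-end run.  Unknown
keys in a YAML override are rejected rather than silently ignored, and the
manifest records a hash of the resolved configuration so two runs can be
compared for parameter identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SynthConfig:
    n_subjects: int = 35
    rr_duration_s: float = 300.0
    n_letters: int = 20
    n_targets: int = 5
    n_trials: int = 6
    per_trial_duration_s: float = 50.0
    mean_rr_ms: float = 800.0
    a_lf: float = 0.04
    a_hf: float = 0.04
    f_lf_hz: float = 0.10
    f_hf_hz: float = 0.25
    jitter_sd_ms: float = 10.0
    subject_rr_sd_ms: float = 50.0
    subject_rt_sd_ms: float = 50.0
    rt_median_ms: float = 500.0
    rt_sigma: float = 0.25
    miss_prob: float = 0.05
    false_alarm_prob: float = 0.02
    effects: str = "default"          # "default" | "identity"
    via_ecg: bool = False             # route through ECG synthesis + detection
    ecg_fs_hz: float = 256.0


@dataclass
class ECGConfig:
    median_window_ms: float = 600.0
    ma_window_ms: float = 20.0
    threshold_fraction: float = 0.4
    refractory_ms: float = 250.0
    clean_window_beats: int = 11
    clean_n_mad: float = 3.0
    rr_bounds_ms: tuple[float, float] = (250.0, 2000.0)


@dataclass
class HRVStageConfig:
    ar_order: int = 16
    resample_hz: float = 4.0
    select_order_aic: bool = False
    mean_hr_instantaneous: bool = True


@dataclass
class StatsConfig:
    holm: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "hrvdt_out"
    synth: SynthConfig = field(default_factory=SynthConfig)
    ecg: ECGConfig = field(default_factory=ECGConfig)
    hrv: HRVStageConfig = field(default_factory=HRVStageConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        cfg = cls()
        for section_name, section_cls in (("synth", SynthConfig), ("ecg", ECGConfig),
                                          ("hrv", HRVStageConfig), ("stats", StatsConfig)):
            sub = data.pop(section_name, {})
            if sub:
                known = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(sub) - known
                if unknown:
                    raise ValueError(f"unknown {section_name} config keys: {sorted(unknown)}")
                setattr(cfg, section_name,
                        dataclasses.replace(getattr(cfg, section_name), **sub))
        known_top = {"seed", "out_dir"}
        unknown = set(data) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in known_top & set(data):
            setattr(cfg, k, data[k])
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
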