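"""Run configuration: one schema-versioned object drives the whole pipeline.

Every default matches the study protocol where one is stated (10 Hz base
rate, oddball every 5th item, 60-s sequences with 2-s fades, 24 sequences
per session, 1024 Hz acquisition, 0.1-100 Hz band-pass, 512 Hz analysis
rate, 500-ms cycle cropping, z thresholds 3.1 / 1.64).  All randomness
flows from the single ``seed``, split per participant and sequence.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

SCHEMA_VERSION = 1


def _default_rois() -> dict[str, list[str]]:
    return {
        "LROI": ["PO7", "P7", "P9", "PO9", "O1"],
        "RROI": ["PO8", "P8", "P10", "PO10", "O2"],
        "MO": ["Oz", "Iz", "O1", "O2"],
    }


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0

    # design
    f_base_hz: float = 10.0
    oddball_every: int = 5
    duration_s: float = 60.0
    fade_in_s: float = 2.0
    fade_out_s: float = 2.0
    n_reps: int = 3
    n_task_events: int = 8
    task_order: tuple[str, str] = ("cross", "bars")

    # synthesis
    n_participants: int = 22
    fs_hz: float = 1024.0
    oddball_amps: tuple[float, ...] = (0.30, 0.22, 0.15, 0.10)
    base_amps: tuple[float, ...] = (1.0, 0.5, 0.25, 0.12)
    pink_exponent: float = 1.0
    pink_scale: float = 0.15
    alpha_amp: float = 0.0
    white_scale: float = 0.02

    # simulated behaviour
    p_hit: float = 0.96
    p_false_alarm: float = 0.05
    rt_mean_s: float = 0.46
    rt_sd_s: float = 0.08

    # preprocessing
    lo_hz: float = 0.1
    hi_hz: float = 100.0
    pre_s: float = 2.0
    post_s: float = 62.0
    target_fs: float = 512.0
    cycle_s: float = 0.5
    interp_k: int = 4

    # statistics
    z_group: float = 3.1
    z_individual: float = 1.64
    oddball_f_max_hz: float = 20.0
    base_f_max_hz: float = 50.0
    individual_z_method: str = "sum"
    response_window_s: tuple[float, float] = (0.15, 1.0)
    rois: dict[str, list[str]] = field(default_factory=_default_rois)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported schema version {self.schema_version}"
            )
        if self.fs_hz < 2 * max(self.base_f_max_hz, self.oddball_f_max_hz):
            raise ConfigurationError("sampling rate below Nyquist for analysis band")
        if self.target_fs > self.fs_hz:
            raise ConfigurationError("analysis rate above acquisition rate")
        n = self.duration_s * self.f_base_hz
        if abs(n - round(n)) > 1e-9 or round(n) % self.oddball_every:
            raise ConfigurationError(
                "duration x base rate must be a multiple of oddball_every"
            )
        if not (0 <= self.lo_hz < self.hi_hz <= self.fs_hz / 2):
            raise ConfigurationError("band-pass edges invalid")
        for name in ("LROI", "RROI", "MO"):
            if name not in self.rois:
                raise ConfigurationError(f"ROI {name!r} missing from config")

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["task_order"] = list(self.task_order)
        doc["oddball_amps"] = list(self.oddball_amps)
        doc["base_amps"] = list(self.base_amps)
        doc["response_window_s"] = list(self.response_window_s)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        for key in ("task_order", "oddball_amps", "base_amps", "response_window_s"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)
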