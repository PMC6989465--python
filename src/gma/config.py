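"""Pipeline configuration with the system's standard defaults.

Defaults reflect the reference recording/analysis protocol: 30 Hz video at
720x480, margins ``t_a1 = t_a2 = 0.02`` and ``t_a3 = 0.03``, reference-frame
count ``E = 10``, movement threshold ``M_th = 0.05``, analysis band up to
``f_max = 5`` Hz, analysis interval ``L = 900`` frames with rhythm
subintervals ``L_f = 300``, Butterworth cutoffs 10 Hz (movement) and 5 Hz
(body centre), and entropy-rejection threshold ``S_th = 1``.  The
binarization threshold ``T`` and the split ratios ``gamma``/``delta`` are
per-video settings (manually adjusted to the recording), so ``threshold``
must be set before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    # per-video (manually adjusted)
    threshold: float | None = None  # binarization threshold T
    gamma: float = 0.5
    delta: float = 0.5
    head_end: str = "top"
    background: str | float = "median"  # "median", a file path, or a constant level

    # measurement / analysis parameters
    f_s: float = 30.0
    t_a1: float = 0.02
    t_a2: float = 0.02
    t_a3: float = 0.03
    e: int = 10
    m_th: float = 0.05
    f_max: float = 5.0
    interval_length: int = 900   # L
    subinterval: int = 300       # L_f
    step: int | None = None      # S; default L (non-overlapping)
    f_cut_m: float = 10.0
    f_cut_g: float = 5.0
    fft_window: int = 128
    fft_overlap: int = 127
    corr_window: int = 300
    corr_overlap: int = 299
    p_ave_mode: str = "mean"
    spread_mode: str = "reciprocal"
    morphological_opening: bool = False

    # classification
    s_th: float = 1.0
    n_components: int = 1
    l2: float = 1.0
    max_iter: int = 500
    entropy_base: float = 2.718281828459045
    seed: int = 0

    def validate(self, *, require_threshold: bool = False) -> None:
        if require_threshold and self.threshold is None:
            raise ConfigError("missing required config key: threshold")
        if self.threshold is not None and not 0 <= self.threshold <= 255:
            raise ConfigError(f"threshold must be in [0, 255], got {self.threshold}")
        if not (0 < self.gamma < 1 and 0 < self.delta < 1):
            raise ConfigError("gamma and delta must lie in (0, 1)")
        if self.interval_length % self.subinterval:
            raise ConfigError("interval_length must be a multiple of subinterval")
        if self.f_cut_m >= self.f_s / 2 or self.f_cut_g >= self.f_s / 2:
            raise ConfigError("filter cutoffs must be below the Nyquist frequency")

    @property
    def effective_step(self) -> int:
        return self.step or self.interval_length

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
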