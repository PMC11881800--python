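"""Declarative pipeline configuration with full validation before execution."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["BootstrapSection", "DekfSection", "CohortSection", "PipelineConfig"]


def _from_mapping(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if hasattr(f.type, "__dataclass_fields__") or f.name in _NESTED:
            val = _NESTED[f.name].from_dict(val)
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class BootstrapSection:
    n_iterations: int = 1000
    n_windows: int = 20
    percentile: float = 99.0
    trt_percentile: float = 95.0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("bootstrap.n_iterations must be >= 1")
        if self.n_windows < 2:
            raise ValueError("bootstrap.n_windows must be >= 2")
        for name in ("percentile", "trt_percentile"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"bootstrap.{name} must be in (0, 100)")

    @classmethod
    def from_dict(cls, d):
        return _from_mapping(cls, dict(d))


@dataclass
class DekfSection:
    state_noise: float | None = None  # None -> adaptive innovation variance
    weight_noise: float = 1e-4
    obs_noise: float | None = None
    init_scale: float = 1.0
    burn_in: int | None = None

    def validate(self) -> None:
        if self.state_noise is not None and self.state_noise <= 0:
            raise ValueError("dekf.state_noise must be positive when fixed")
        if self.weight_noise <= 0:
            raise ValueError("dekf.weight_noise must be positive")
        if self.init_scale <= 0:
            raise ValueError("dekf.init_scale must be positive")

    @classmethod
    def from_dict(cls, d):
        return _from_mapping(cls, dict(d))


@dataclass
class CohortSection:
    n_ci: int = 50
    n_th: int = 25
    n_boot: int = 5000

    def validate(self) -> None:
        if self.n_ci <= 0 or self.n_th <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.n_boot < 0:
            raise ValueError("cohort.n_boot must be >= 0")

    @classmethod
    def from_dict(cls, d):
        return _from_mapping(cls, dict(d))


_NESTED: dict = {}


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; defaults mirror the published analysis
    settings (0.009-0.08 Hz band, wavelet alpha 0.1, 1000-iteration bootstrap
    at the 99th percentile)."""

    fs: float = 7.8125
    duration_s: float = 420.0
    band: tuple = (0.009, 0.08)
    n_freq: int = 64
    wavelet_alpha: float = 0.1
    chromophore: str = "HbO"
    hemisphere_policy: str = "average"  # average | left | right
    order: int | None = None
    order_range: tuple = (1, 8)
    n_nirs_subjects: int = 2
    edge_density: float = 0.2
    seed: int = 0
    bootstrap: BootstrapSection = field(default_factory=BootstrapSection)
    dekf: DekfSection = field(default_factory=DekfSection)
    cohort: CohortSection = field(default_factory=CohortSection)
    output_dir: str = "nirsconn_output"

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if hi > self.fs / 2:
            raise ValueError(
                f"band upper edge {hi} Hz exceeds Nyquist {self.fs / 2} Hz"
            )
        if self.n_freq < 1:
            raise ValueError("n_freq must be >= 1")
        if not 0 < self.wavelet_alpha < 1:
            raise ValueError("wavelet_alpha must be in (0, 1)")
        if self.chromophore not in ("HbO", "HbR"):
            raise ValueError("chromophore must be HbO or HbR")
        if self.hemisphere_policy not in ("average", "left", "right"):
            raise ValueError("hemisphere_policy must be average, left or right")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must be in [0, 1]")
        if self.n_nirs_subjects < 1:
            raise ValueError("n_nirs_subjects must be >= 1")
        self.bootstrap.validate()
        self.dekf.validate()
        self.cohort.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = _from_mapping(cls, dict(data))
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        if isinstance(cfg.order_range, list):
            cfg.order_range = tuple(cfg.order_range)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


_NESTED.update(
    {"bootstrap": BootstrapSection, "dekf": DekfSection, "cohort": CohortSection}
)
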