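"""Typed pipeline configuration with strict key checking.

Every section mirrors one module's parameters; unknown keys are rejected so
a typo cannot silently fall back to a default.  The fully resolved config is
logged (and written next to demo outputs) for every run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PhantomConfig:
    pixel_pitch_um: float = 200.0
    pixel_gain_sigma: float = 0.2
    mz_jitter_sigma_at_ref: float = 0.001
    background_peak_rate: float = 2.0


@dataclass
class AcquisitionConfig:
    velocity_x_um_s: float = 160.0
    line_step_um: float = 200.0
    scan_period_s: float = 1.25


@dataclass
class AxisConfig:
    mz_lo: float = 400.0
    mz_hi: float = 1000.0
    ref_mz: float = 850.0
    ref_bin_width: float = 0.02
    ref_sigma: float = 0.001


@dataclass
class NmfConfig:
    ks: list[int] = field(default_factory=lambda: [1, 2, 5])
    tol: float = 1e-6
    max_iter: int = 500


@dataclass
class KMeansConfig:
    k: int = 5
    n_init: int = 10
    max_iter: int = 300


@dataclass
class AnnotationConfig:
    cross_reference_tol_mz: float = 0.005
    ion_image_tol_mz: float = 0.05
    isotope_tol_mz: float = 0.05
    major_peak_threshold_percent: float = 5.0


@dataclass
class SerumConfig:
    n_case: int = 14
    n_control: int = 11
    effect_scale: float = 1.0
    sigma: float = 0.2


@dataclass
class ClassificationConfig:
    n_orth: int = 1
    autoscale: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    axis: AxisConfig = field(default_factory=AxisConfig)
    nmf: NmfConfig = field(default_factory=NmfConfig)
    kmeans: KMeansConfig = field(default_factory=KMeansConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    serum: SerumConfig = field(default_factory=SerumConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any] | None) -> "PipelineConfig":
        return _build(cls, data or {}, path="")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _build(cls, data: Mapping[str, Any], path: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"section {path or '<root>'} must be a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {path or '<root>'}; "
            f"valid keys: {sorted(fields)}"
        )
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        value = data[name]
        if dataclasses.is_dataclass(f.type) or (isinstance(f.type, type) and dataclasses.is_dataclass(f.type)):
            kwargs[name] = _build(f.type, value, path=f"{path}.{name}".lstrip("."))
        else:
            kwargs[name] = value
    # handle dataclass fields declared via default_factory on PipelineConfig
    for name, f in fields.items():
        default = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
        if name in data and dataclasses.is_dataclass(default):
            kwargs[name] = _build(type(default), data[name], path=f"{path}.{name}".lstrip("."))
    return cls(**kwargs)
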