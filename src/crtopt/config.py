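"""Pipeline configuration.

One YAML-serializable dataclass per pipeline stage, gathered in
:class:`PipelineConfig`.  Every printed constant of the method lives here
with its default: the 4:1 anisotropy, the 0.5 fibrosis conductivity factor,
the kappa range [0.2, 1.5], the 0.85 correlation filter, the 0.51 response
cutoff, the mu + 2*sigma acquisition coefficient and the 0.5 score-map
threshold.  Unknown keys fail fast at load time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class GeometryConfig:
    lv_endo_radius: float = 22.0
    lv_endo_length: float = 40.0
    lv_wall: float = 10.0
    spacing: float = 4.0
    seed: int = 0


@dataclass
class ConductionConfig:
    v_f: float = 0.65
    rho: float = 4.0
    kappa: float = 1.0
    fibrosis_factor: float = 0.5
    kappa_min: float = 0.2
    kappa_max: float = 1.5


@dataclass
class EcgConfig:
    dt: float = 1.0
    detector_threshold: float = 0.02
    debounce_ms: float = 5.0


@dataclass
class ClassifierConfig:
    cutoff: float = 0.51
    corr_threshold: float = 0.85
    selector: str = "univariate-rank"
    n_select: int = 7


@dataclass
class OptimizerConfig:
    acquisition_coef: float = 2.0
    max_iter: int = 30
    map_threshold: float = 0.5
    site_tol_mm: float = 0.0
    seed: int = 0


@dataclass
class CohortConfig:
    n: int = 5
    seed: int = 0
    scar_probability: float = 0.5


@dataclass
class PipelineConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    conduction: ConductionConfig = field(default_factory=ConductionConfig)
    ecg: EcgConfig = field(default_factory=EcgConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        known = {f.name: f for f in fields(cls)}
        for key, sub in (data or {}).items():
            if key not in known:
                raise ValueError(f"unknown configuration section {key!r}")
            sub_cls = known[key].default_factory  # type: ignore[union-attr]
            sub_fields = {f.name for f in fields(sub_cls())}
            unknown = set(sub or {}) - sub_fields
            if unknown:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            kwargs[key] = type(sub_cls())(**(sub or {}))
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
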