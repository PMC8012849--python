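"""Run configuration: every stage's parameters with validated defaults.

The configuration is a plain nested dataclass serializable to/from YAML or
JSON; its SHA-256 hash is embedded in every output file for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .actuate import ExoskeletonConfig
from .optics import DEFAULT_WAVELENGTHS
from .synthesize import SubjectConfig

__all__ = ["RunConfig"]


@dataclass
class ParadigmParams:
    levels: tuple[str, ...] = ("mwl1", "mwl2")
    n_trials: int = 10
    task_s: float = 20.0
    rest_s: float = 20.0
    baseline_s: float = 146.0
    inter_level_delay_s: float = 25.0
    sampling_rate: float = 8.0


@dataclass
class OpticsParams:
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    path_length_cm: float = 3.0
    dpf: float = 6.0


@dataclass
class FilterParams:
    cutoff_hz: float = 0.3
    order: int = 4


@dataclass
class QCParams:
    alpha: float = 0.05
    threshold: float = 0.8916
    bonferroni: bool = False


@dataclass
class FeatureParams:
    window_s: float = 2.0
    step_s: float = 1.0
    feature_set: tuple[str, ...] = ("mean", "slope")
    channel_average: bool = False


@dataclass
class ClassifierParams:
    C: float = 1.0
    test_fraction: float = 0.3
    by_epoch: bool = False


@dataclass
class ActuationParams:
    stroke_max_mm: float = 25.5
    rom_deg: tuple[float, float, float] = (63.1, 118.2, 63.1)
    actuation_time_s: float = 1.0
    confidence_threshold: float = 0.0
    dt_s: float = 0.05

    def to_exo_config(self) -> ExoskeletonConfig:
        return ExoskeletonConfig(
            stroke_max_mm=self.stroke_max_mm,
            rom_deg=tuple(self.rom_deg),
            actuation_time_s=self.actuation_time_s,
        )


@dataclass
class GeneratorParams:
    amplitude_mwl1: float = 0.5
    amplitude_mwl2: float = 1.0
    hbr_ratio: float = -1.0 / 3.0
    noise_sd: float = 0.3
    physio: tuple[tuple[float, float], ...] = ((1.1, 0.1), (0.25, 0.15), (0.1, 0.1))
    n_channels: int = 12
    bad_channels: tuple[int, ...] = ()

    def to_subject_config(self, seed: int) -> SubjectConfig:
        return SubjectConfig(
            amplitude_mwl1=self.amplitude_mwl1,
            amplitude_mwl2=self.amplitude_mwl2,
            hbr_ratio=self.hbr_ratio,
            noise_sd=self.noise_sd,
            physio=tuple(tuple(p) for p in self.physio),
            n_channels=self.n_channels,
            bad_channels=frozenset(self.bad_channels),
            seed=seed,
        )


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run."""

    seed: int = 0
    input_path: "str | None" = None  # None = simulate
    output_dir: str = "nirsbmi_out"
    output_format: str = "tsv"  # recording format: "tsv" or "snirf"
    paradigm: ParadigmParams = field(default_factory=ParadigmParams)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    filter: FilterParams = field(default_factory=FilterParams)
    qc: QCParams = field(default_factory=QCParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    actuation: ActuationParams = field(default_factory=ActuationParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self.paradigm
        if p.sampling_rate <= 0:
            raise ValueError("paradigm.sampling_rate must be > 0")
        if self.filter.cutoff_hz >= p.sampling_rate / 2:
            raise ValueError("filter.cutoff_hz must be below the Nyquist frequency")
        if not 0 < self.qc.alpha <= 1:
            raise ValueError("qc.alpha must lie in (0, 1]")
        if not 0 <= self.qc.threshold <= 1:
            raise ValueError("qc.threshold must lie in [0, 1]")
        if not 0 < self.classifier.test_fraction < 1:
            raise ValueError("classifier.test_fraction must lie in (0, 1)")
        if self.output_format not in ("tsv", "snirf"):
            raise ValueError("output_format must be 'tsv' or 'snirf'")
        # Delegate the rest to the stage dataclasses.
        self.generator.to_subject_config(self.seed)
        self.actuation.to_exo_config()

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        """SHA-256 over the scientific parameters (first 16 hex digits).

        Input/output locations are excluded so the same analysis written to
        two directories carries the same hash.
        """
        d = self.to_dict()
        d.pop("input_path", None)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)

        def load(key, klass):
            if key in data and isinstance(data[key], dict):
                data[key] = klass(**_tupled(data[key]))

        load("paradigm", ParadigmParams)
        load("generator", GeneratorParams)
        load("optics", OpticsParams)
        load("filter", FilterParams)
        load("qc", QCParams)
        load("features", FeatureParams)
        load("classifier", ClassifierParams)
        load("actuation", ActuationParams)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _tupled(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out
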