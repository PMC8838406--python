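"""Pipeline configuration: one YAML-serializable bundle of stage configs."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .filterbank import FusionConfig, KernelSpec
from .postprocess import PostprocessConfig
from .preprocessing import MSRConfig
from .thresholding import PSOConfig


@dataclass(frozen=True)
class PipelineConfig:
    """All stage settings of the segmentation pipeline.

    ``n_thresholds`` is the multilevel-Otsu order m (3 by default: three
    thresholds, four gray classes).  ``seed`` is the single pipeline
    seed from which per-stage seeds are derived.
    """

    msr: MSRConfig = field(default_factory=MSRConfig)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    n_thresholds: int = 3
    post: PostprocessConfig = field(default_factory=PostprocessConfig)
    seed: int = 0

    def validate(self) -> None:
        self.msr.validate()
        self.kernel.validate()
        self.fusion.validate()
        self.pso.validate()
        self.post.validate()
        if self.n_thresholds < 1:
            raise ConfigurationError("n_thresholds must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {
            "msr": MSRConfig,
            "kernel": KernelSpec,
            "fusion": FusionConfig,
            "pso": PSOConfig,
            "post": PostprocessConfig,
        }
        kwargs = {}
        for key, sub_cls in known.items():
            if key in data:
                sub = data.pop(key)
                if not isinstance(sub, dict):
                    raise ConfigurationError(f"config section {key!r} must be a mapping")
                try:
                    kwargs[key] = _build(sub_cls, sub)
                except TypeError as exc:
                    raise ConfigurationError(f"bad {key} config: {exc}") from exc
        for key in ("n_thresholds", "seed"):
            if key in data:
                kwargs[key] = int(data.pop(key))
        if data:
            raise ConfigurationError(f"unknown config keys: {sorted(data)}")
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=int(seed))


def _build(sub_cls, data: dict):
    # tuples arrive from YAML as lists; dataclass fields expect tuples
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return sub_cls(**coerced)


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
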