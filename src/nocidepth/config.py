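"""Analysis configuration: defaults, YAML loading, and config hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classical import POINT_TOL, TRIANGLE_TOL
from .likelihood import MLESearchConfig
from .priors import PriorSpec
from .selection import EvidenceConfig
from .thermal import CONVENTIONS, ConfigurationError, PAPER_SQRT


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the pipeline; unspecified fields take these defaults."""

    prior: PriorSpec = field(default_factory=PriorSpec)
    rate_lambda: float = 1.0
    alpha_convention: str = PAPER_SQRT
    point_tol: tuple = POINT_TOL
    triangle_tol: tuple = TRIANGLE_TOL
    mle: MLESearchConfig = field(default_factory=MLESearchConfig)
    evidence: EvidenceConfig = field(default_factory=EvidenceConfig)
    mc_depth_samples: int = 100_000
    gamma_prior_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_convention not in CONVENTIONS:
            raise ConfigurationError(
                f"alpha_convention must be one of {CONVENTIONS}")
        if self.rate_lambda <= 0:
            raise ConfigurationError("rate_lambda must be positive")

    def to_dict(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return unpack(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d or {})
        kwargs = {}
        if "prior" in d:
            p = dict(d.pop("prior"))
            for key in ("k_range", "rho_range", "c_range"):
                if key in p:
                    p[key] = tuple(p[key])
            kwargs["prior"] = PriorSpec(**p)
        if "mle" in d:
            kwargs["mle"] = MLESearchConfig(**d.pop("mle"))
        if "evidence" in d:
            e = dict(d.pop("evidence"))
            if "lambda_s_range" in e:
                e["lambda_s_range"] = tuple(e["lambda_s_range"])
            kwargs["evidence"] = EvidenceConfig(**e)
        for key in ("point_tol", "triangle_tol"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
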