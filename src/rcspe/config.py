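"""Validated pipeline configuration (YAML/JSON-loadable).

Defaults reproduce the method's published settings: the 6 x 5 (beta, gamma)
grid, m = 5 (clamped to floor(N/2) on narrow channel sets), k = 15,
city-block KNN metric and 5-fold cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .ensemble import DEFAULT_BETAS, DEFAULT_GAMMAS, DEFAULT_K, DEFAULT_M
from .errors import InvalidInputError


@dataclass
class ModelConfig:
    betas: tuple[float, ...] = DEFAULT_BETAS
    gammas: tuple[float, ...] = DEFAULT_GAMMAS
    m: int = DEFAULT_M
    k: int = DEFAULT_K
    metric: str = "cityblock"
    allow_overlap: bool = False
    inner_folds: int = 5

    def __post_init__(self) -> None:
        self.betas = tuple(float(b) for b in self.betas)
        self.gammas = tuple(float(g) for g in self.gammas)
        for v in self.betas + self.gammas:
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"regularization value {v} outside [0, 1]")
        if self.k % 2 == 0 or not 1 <= self.k <= 20:
            raise InvalidInputError("k must be an odd number not greater than 20")
        if self.m < 1:
            raise InvalidInputError("m must be >= 1")
        if self.metric not in ("cityblock", "euclidean"):
            raise InvalidInputError(f"unsupported metric '{self.metric}'")
        if self.inner_folds < 2:
            raise InvalidInputError("inner_folds must be >= 2")


@dataclass
class EvaluationConfig:
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise InvalidInputError("folds must be >= 2")


@dataclass
class PipelineConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    methods: tuple[str, ...] = ("rcspe", "csp", "rcspcv", "hbo")

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON config; missing blocks fall back to defaults."""
    if path is None:
        return PipelineConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise InvalidInputError("config root must be a mapping")
    known = {"model", "evaluation", "methods"}
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(
        model=_build(ModelConfig, data.get("model", {}) or {}),
        evaluation=_build(EvaluationConfig, data.get("evaluation", {}) or {}),
        methods=tuple(data.get("methods", ("rcspe", "csp", "rcspcv", "hbo"))),
    )


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, default=list))
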