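"""Configuration objects for the analysis functions, pipeline and CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "PipelineConfig"]

_VALID_NORMS = ("euclidean", "maximum")
_VALID_SCOPES = ("panel", "global")


@dataclass
class AnalysisConfig:
    """Knobs for a single pair / panel analysis.

    ``epsilon_fraction`` defaults to the conventional 0.6% of the joint
    phase-space diameter; ``score_floor`` optionally lifts min-max
    normalized indices off exact zero before the geometric mean so that
    a single worst index does not annihilate a score.
    """

    epsilon_fraction: float = 0.006
    norm: str = "euclidean"
    lmin: int = 2
    vmin: int = 2
    mi_bins: int = 16
    ami_bins: int = 16
    max_delay: int = 60
    max_dim: int = 10
    fnn_rtol: float = 15.0
    fnn_atol: float = 2.0
    fnn_threshold: float = 0.01
    fnn_max_points: int | None = 2000
    standardize: bool = True
    normalization_scope: str = "panel"
    param_scope: str = "pair"
    score_floor: float = 0.0

    def validate(self) -> "AnalysisConfig":
        if not 0 < self.epsilon_fraction < 1:
            raise ValueError("epsilon_fraction must lie in (0, 1)")
        if self.norm not in _VALID_NORMS:
            raise ValueError(f"norm must be one of {_VALID_NORMS}")
        if self.normalization_scope not in _VALID_SCOPES:
            raise ValueError(f"normalization_scope must be one of {_VALID_SCOPES}")
        if self.param_scope not in ("pair", "panel"):
            raise ValueError("param_scope must be 'pair' or 'panel'")
        for name in ("lmin", "vmin", "mi_bins", "ami_bins", "max_delay", "max_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mi_bins < 2 or self.ami_bins < 2:
            raise ValueError("bin counts must be >= 2")
        if not 0 <= self.score_floor < 1:
            raise ValueError("score_floor must lie in [0, 1)")
        if self.fnn_rtol <= 0 or self.fnn_atol <= 0 or not 0 < self.fnn_threshold < 1:
            raise ValueError("invalid FNN criteria")
        return self


@dataclass
class PipelineConfig(AnalysisConfig):
    """Full pipeline run: targets, record lengths, output knobs.

    ``lengths`` lists record truncations for the sensitivity study
    (``None`` stands for the full record); an empty tuple skips it.
    """

    targets: list[tuple[str, str]] | None = None
    center_station: str | None = None
    lengths: tuple = (2000, 3000, None)
    render_crps: bool = True
    max_gap: int = 3
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        super().validate()
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        for length in self.lengths:
            if length is not None and length < 2:
                raise ValueError(f"invalid record length {length}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "targets" in raw and raw["targets"] is not None:
            raw["targets"] = [tuple(t) for t in raw["targets"]]
        if "lengths" in raw and raw["lengths"] is not None:
            raw["lengths"] = tuple(raw["lengths"])
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["lengths"] = list(self.lengths)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
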