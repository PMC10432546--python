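"""Run configuration: every tunable of the pipeline under one namespace.

A :class:`RunConfig` groups the per-module parameter dataclasses and maps
to/from a flat JSON document of dotted keys (``"separator.chunk_size"``).
Unknown keys are rejected with the list of valid keys; values are
validated by each section's own constructor; an empty document yields the
full default configuration, and save(load(x)) is the identity on
normalized documents.
"""

from __future__ import annotations

import dataclasses
import json

from .predictability import DEFAULT_TAU_GRID  # noqa: F401  (re-exported default)
from .separator.network import SeparatorConfig
from .synthesize import SimulationSpec


@dataclasses.dataclass
class PseudoBulkConfig:
    """Pseudo-bulk pair construction (the published protocol's numbers)."""

    pairs_per_subject: int = 3000
    min_cells: int = 100
    max_cells: int = 800
    seed: int = 0

    def __post_init__(self):
        if self.pairs_per_subject <= 0:
            raise ValueError("pairs_per_subject must be > 0")
        if not (0 < self.min_cells <= self.max_cells):
            raise ValueError("need 0 < min_cells <= max_cells")


@dataclasses.dataclass
class FilterConfig:
    """NMEA predictability filter settings."""

    tau: float | None = None  # None = optimize on validation pairs
    grid_start: float = -0.5
    grid_stop: float = 1.0
    grid_step: float = 0.1
    max_pairs: int = 100

    def __post_init__(self):
        if self.tau is not None and not (-0.5 <= self.tau <= 1.0):
            raise ValueError("tau must be in [-0.5, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")


@dataclasses.dataclass
class EvaluationConfig:
    baseline_train_pairs: int = 100
    knn_k: int = 5
    n_random_replicates: int = 100
    cv_folds: int = 5
    classifier_learning_rate: float = 0.1
    classifier_max_depth: int = 10
    classifier_n_estimators: int = 100
    seed: int = 0


@dataclasses.dataclass
class DownstreamConfig:
    alpha: float = 0.05
    fc_min: float = 0.5

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_min < 0:
            raise ValueError("fc_min must be >= 0")


_SECTIONS = {
    "simulation": SimulationSpec,
    "pseudobulk": PseudoBulkConfig,
    "separator": SeparatorConfig,
    "filter": FilterConfig,
    "evaluation": EvaluationConfig,
    "downstream": DownstreamConfig,
}


@dataclasses.dataclass
class RunConfig:
    simulation: SimulationSpec = dataclasses.field(default_factory=SimulationSpec)
    pseudobulk: PseudoBulkConfig = dataclasses.field(default_factory=PseudoBulkConfig)
    separator: SeparatorConfig = dataclasses.field(default_factory=SeparatorConfig)
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    evaluation: EvaluationConfig = dataclasses.field(default_factory=EvaluationConfig)
    downstream: DownstreamConfig = dataclasses.field(default_factory=DownstreamConfig)

    def to_flat_dict(self) -> dict:
        flat = {}
        for sec in _SECTIONS:
            obj = getattr(self, sec)
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, tuple):
                    v = list(v)
                flat[f"{sec}.{f.name}"] = v
        return flat

    @classmethod
    def valid_keys(cls) -> list[str]:
        return [
            f"{sec}.{f.name}"
            for sec, typ in _SECTIONS.items()
            for f in dataclasses.fields(typ)
        ]

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "RunConfig":
        valid = set(cls.valid_keys())
        unknown = sorted(set(flat) - valid)
        if unknown:
            raise ValueError(
                f"unknown configuration keys: {unknown}; valid keys are "
                f"{sorted(valid)}"
            )
        per_section: dict[str, dict] = {sec: {} for sec in _SECTIONS}
        for key, value in flat.items():
            sec, field = key.split(".", 1)
            default = getattr(_SECTIONS[sec](), field, None)
            if isinstance(default, tuple) and isinstance(value, list):
                value = tuple(value)
            per_section[sec][field] = value
        return cls(**{sec: typ(**per_section[sec]) for sec, typ in _SECTIONS.items()})


def load_config(path) -> RunConfig:
    """Load a (possibly partial) JSON configuration; defaults fill gaps."""
    with open(path) as fh:
        flat = json.load(fh)
    if not isinstance(flat, dict):
        raise ValueError(f"{path}: configuration must be a JSON object")
    return RunConfig.from_flat_dict(flat)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_flat_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
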