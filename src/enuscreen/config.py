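"""Run configuration: one structured file driving the whole pipeline.

Defaults mirror the screen's operating point: 6X minimum depth, 10^6
permutations, genome-wide LOD threshold 3.3, FDR reporting lines
{0.1, 0.25, 0.8}, 2% phenocopy rate, 33% suppressor penetrance. Unknown
keys are rejected so typos fail fast rather than silently reverting to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "SimulateParams", "FilterParams", "BurdenParams",
           "LinkageParams", "CrossParams", "ConfigError"]


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"{cls.__name__} section must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimulateParams:
    n_genes: int = 2_000
    n_g1_mice: int = 107
    exonic_rate_lambda: float = 65.0
    n_suppressor_genes: int = 30
    penetrance: float = 0.33
    phenocopy_rate: float = 0.02
    de_novo_rate: float = 5.4e-9
    artifact_rate: float = 175.0
    depth_mean: float = 77.0
    low_coverage_fraction: float = 0.04
    female_fraction: float = 0.5


@dataclass(frozen=True)
class FilterParams:
    min_depth: int = 6
    include_stoploss: bool = False


@dataclass(frozen=True)
class BurdenParams:
    n_perm: int = 1_000_000
    fdr_lines: tuple = (0.1, 0.25, 0.8)


@dataclass(frozen=True)
class LinkageParams:
    lod_threshold: float = 3.3
    theta_marker_trait: float = 0.141
    n_offspring_per_generation: int = 8
    generations: int = 3
    power_n_sim: int = 2_000
    power_n_markers: int = 20
    power_theta_true: float = 0.141


@dataclass(frozen=True)
class CrossParams:
    table: str | None = None  # path; None -> bundled validation-cross table


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    simulate: SimulateParams = field(default_factory=SimulateParams)
    filter: FilterParams = field(default_factory=FilterParams)
    burden: BurdenParams = field(default_factory=BurdenParams)
    linkage: LinkageParams = field(default_factory=LinkageParams)
    cross: CrossParams = field(default_factory=CrossParams)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "simulate": SimulateParams,
            "filter": FilterParams,
            "burden": BurdenParams,
            "linkage": LinkageParams,
            "cross": CrossParams,
        }
        kwargs = {}
        for key, section_cls in sections.items():
            if key in data:
                kwargs[key] = _from_dict(section_cls, data.pop(key))
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs.update(data)
        cfg = cls(**kwargs)
        if isinstance(cfg.burden.fdr_lines, list):
            object.__setattr__(cfg.burden, "fdr_lines", tuple(cfg.burden.fdr_lines))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["burden"]["fdr_lines"] = list(self.burden.fdr_lines)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def non_default_items(self) -> dict:
        """Flat view of every parameter that differs from its default (logged
        with each run for reproducibility)."""
        default = RunConfig()
        out = {}
        for f in dataclasses.fields(self):
            v, d = getattr(self, f.name), getattr(default, f.name)
            if dataclasses.is_dataclass(v):
                for sf in dataclasses.fields(v):
                    sv, sd = getattr(v, sf.name), getattr(d, sf.name)
                    if sv != sd:
                        out[f"{f.name}.{sf.name}"] = sv
            elif v != d:
                out[f.name] = v
        return out
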