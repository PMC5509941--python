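"""Pipeline configuration: one JSON document drives every stage."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields

__all__ = ["SearchlightConfig", "GroupStatsConfig", "PipelineConfig"]


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_dict(f.type, value)
        elif f.name in ("searchlight", "group") and isinstance(value, dict):
            value = _from_dict(_NESTED[f.name], value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class SearchlightConfig:
    radius: int = 3
    scatter_step: int = 3
    repetitions: int = 10
    ridge_lambda: float = 1.0
    min_sphere_voxels: int = 3


@dataclass
class GroupStatsConfig:
    n_null: int = 20
    null_repetitions: int = 2
    n_bootstrap: int = 10000
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    connectivity: str = "faces"


_NESTED = {"searchlight": SearchlightConfig, "group": GroupStatsConfig}


@dataclass
class PipelineConfig:
    """All stage parameters for a synthetic end-to-end run.

    Defaults are desk-scale: a small grid, few subjects, and reduced null /
    bootstrap counts. Field values mirror the analysis defaults documented
    on each stage function.
    """

    seed: int = 0
    n_subjects: int = 4
    grid_shape: tuple = (24, 24, 24)
    slab_thickness: int = 2
    snr: float = 1.0
    n_runs: int = 8
    volumes_per_run: int = 153
    tr: float = 2.0
    n_select_voxels: int = 5000
    min_variance: float = 0.95
    feature_kinds: tuple = ("melody_abs", "melody_rel", "chroma")
    do_decoding: bool = True
    do_searchlight: bool = True
    searchlight: SearchlightConfig = field(default_factory=SearchlightConfig)
    group: GroupStatsConfig = field(default_factory=GroupStatsConfig)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(self.grid_shape)
        self.feature_kinds = tuple(self.feature_kinds)
        if isinstance(self.searchlight, dict):
            self.searchlight = _from_dict(SearchlightConfig, self.searchlight)
        if isinstance(self.group, dict):
            self.group = _from_dict(GroupStatsConfig, self.group)
        for kind in self.feature_kinds:
            if kind not in ("melody_abs", "melody_rel", "chroma"):
                raise ValueError(f"unknown feature kind {kind!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
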