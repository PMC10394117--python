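"""Run configuration with lossless YAML round-tripping.

A :class:`RunConfig` bundles everything a study run needs - phantom and
motion parameters, noise models, imaging geometry, network and schedule
settings, scenario selection and the master seed - and serializes to a flat
YAML document so runs are reproducible from a single file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path

import yaml

from .bionet import BioUNetConfig
from .grid import GridSpec
from .phantom import MotionParams, PhantomConfig
from .projection import PhotonNoiseConfig, ProjectionGeometry
from .study import StudyConfig
from .surface import SurfaceNoiseConfig
from .surfnet import SurfNetConfig
from .xnet import XLossWeights, XNetConfig

__all__ = ["RunConfig", "to_dict", "from_dict"]

_TYPES = {cls.__name__: cls for cls in (
    StudyConfig, PhantomConfig, MotionParams, GridSpec, SurfaceNoiseConfig,
    ProjectionGeometry, PhotonNoiseConfig, SurfNetConfig, XNetConfig,
    XLossWeights, BioUNetConfig,
)}


def to_dict(obj):
    """Recursively convert (nested) dataclasses to plain YAML-safe data."""
    if is_dataclass(obj) and not isinstance(obj, type):
        out = {"__type__": type(obj).__name__}
        for f in dataclasses.fields(obj):
            out[f.name] = to_dict(getattr(obj, f.name))
        return out
    if isinstance(obj, (list, tuple)):
        return [to_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: to_dict(v) for k, v in obj.items()}
    return obj


def from_dict(data):
    """Inverse of :func:`to_dict` (tuples are restored for tuple fields)."""
    if isinstance(data, dict) and "__type__" in data:
        cls = _TYPES[data["__type__"]]
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            v = from_dict(data[f.name])
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)
    if isinstance(data, list):
        return [from_dict(v) for v in data]
    if isinstance(data, dict):
        return {k: from_dict(v) for k, v in data.items()}
    return data


@dataclass(frozen=True)
class RunConfig:
    """Top-level run description: study settings, seed, outputs."""

    study: StudyConfig = field(default_factory=StudyConfig.small)
    seed: int = 0
    scenario_types: tuple = (1, 2, 3, 4)
    variants: tuple = ("prior", "surf-bio", "x-bio", "surf-x-bio")
    robustness_offsets: tuple = (0.0, 1.0, 2.0)
    output_dir: str = "scratch/run"

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(to_dict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        text = str(path_or_text)
        if "\n" not in text:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        data = yaml.safe_load(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = from_dict(data[f.name])
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)
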