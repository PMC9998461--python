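"""Run configuration: nested YAML sections mirroring each module's config.

Unknown keys are rejected so typos fail loudly, and a serialised snapshot
is written into every output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .mil import ClsConfig
from .phantom import PhantomConfig
from .pipeline import PipelineConfig
from .segmentation import SegConfig

__all__ = ["RunConfig", "load_config", "snapshot_config"]

_SECTIONS = {
    "phantom": PhantomConfig,
    "segmentation": SegConfig,
    "classifier": ClsConfig,
    "pipeline": PipelineConfig,
}


@dataclasses.dataclass
class RunConfig:
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    segmentation: SegConfig = dataclasses.field(default_factory=SegConfig)
    classifier: ClsConfig = dataclasses.field(default_factory=ClsConfig)
    pipeline: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)
    seed: int = 0
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        out = {}
        for section, cls in _SECTIONS.items():
            out[section] = dataclasses.asdict(getattr(self, section))
        out["seed"] = self.seed
        out["out_dir"] = self.out_dir
        return out


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for key, value in overrides.items():
            section, _, field = key.partition(".")
            if field:
                data.setdefault(section, {})[field] = value
            else:
                data[key] = value
    known = set(_SECTIONS) | {"seed", "out_dir"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            kwargs[section] = _build_section(cls, data[section] or {}, section)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "out_dir" in data:
        kwargs["out_dir"] = str(data["out_dir"])
    return RunConfig(**kwargs)


def snapshot_config(config: RunConfig, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
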