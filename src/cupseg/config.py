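"""YAML configuration for the pipeline.

A config file may use nested sections or flat dotted keys (or a mix):

    enhance:
      se_size: 5
    vessels.median_size: 9
    lcv:
      alpha: 0.1

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ParameterError
from .pipeline import PipelineConfig

_SECTIONS = ("enhance", "vessels", "bscb", "lcv")
_TOPLEVEL = ("roi_margin", "use_enhance", "use_inpaint")


def default_config() -> PipelineConfig:
    return PipelineConfig()


def set_param(cfg: PipelineConfig, dotted: str, value) -> PipelineConfig:
    """Return a copy of ``cfg`` with one dotted key replaced."""
    if dotted in _TOPLEVEL:
        return dataclasses.replace(cfg, **{dotted: value})
    if "." not in dotted:
        raise ParameterError(f"unknown config key {dotted!r}")
    section, name = dotted.split(".", 1)
    if section not in _SECTIONS:
        raise ParameterError(f"unknown config section {section!r}")
    sub = getattr(cfg, section)
    if name not in {f.name for f in dataclasses.fields(sub)}:
        raise ParameterError(f"unknown config key {dotted!r}")
    return dataclasses.replace(cfg, **{section: dataclasses.replace(sub, **{name: value})})


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML file onto the default configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, value in data.items():
        if isinstance(value, dict):
            for name, v in value.items():
                cfg = set_param(cfg, f"{key}.{name}", v)
        else:
            cfg = set_param(cfg, key, value)
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the full configuration as nested YAML."""
    data = {s: dataclasses.asdict(getattr(cfg, s)) for s in _SECTIONS}
    for key in _TOPLEVEL:
        data[key] = getattr(cfg, key)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
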