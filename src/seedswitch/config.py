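"""Flat YAML configuration I/O for model parameters and run provenance."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import ModelParameters

__all__ = ["load_parameters", "save_parameters", "write_provenance"]


def load_parameters(path=None) -> ModelParameters:
    """Read a flat key: value YAML file into :class:`ModelParameters`.

    ``None`` or the literal string ``"default"`` return the defaults.  Keys
    use ASCII transliterations of the model symbols (``theta_I_ABA`` etc.);
    unspecified keys fall back to defaults, unknown keys raise (typo
    protection), non-positive values raise.
    """
    if path is None or str(path) == "default":
        return ModelParameters()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return ModelParameters()
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameter keys")
    for key, value in data.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(f"{path}: parameter {key!r} must be numeric, got {value!r}")
    return ModelParameters.from_dict(data)


def save_parameters(p: ModelParameters, path) -> None:
    Path(path).write_text(yaml.safe_dump(p.to_dict(), sort_keys=False))


def write_provenance(path, record: dict) -> None:
    """JSON provenance sidecar with resolved parameters and seeds."""
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
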