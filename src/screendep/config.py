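"""YAML configuration loading for the pipeline.

A run configuration has optional ``hyperparams``, ``fit`` and ``sim``
sections mapping directly onto :class:`Hyperparams`, :class:`FitConfig` and
:class:`SimConfig`; unknown keys are rejected so typos fail before any
computation.  The resolved configuration is re-serialized into every output
directory for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .inference import FitConfig
from .model import Hyperparams
from .simulate import SimConfig

__all__ = ["load_yaml", "hyperparams_from_dict", "fit_config_from_dict",
           "sim_config_from_dict", "dump_resolved_config"]


def load_yaml(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping: {path}")
    return data


def _from_dict(cls, payload: dict | None, section: str):
    payload = dict(payload or {})
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown keys in {section!r} section: {sorted(unknown)}")
    for key in ("q_range", "gamma_range", "noise_sd_range",
                "gene_efficacy_beta", "seed_efficacy_beta"):
        if key in payload and isinstance(payload[key], list):
            payload[key] = tuple(payload[key])
    return cls(**payload)


def hyperparams_from_dict(payload: dict | None) -> Hyperparams:
    return _from_dict(Hyperparams, payload, "hyperparams")


def fit_config_from_dict(payload: dict | None) -> FitConfig:
    return _from_dict(FitConfig, payload, "fit")


def sim_config_from_dict(payload: dict | None) -> SimConfig:
    return _from_dict(SimConfig, payload, "sim")


def dump_resolved_config(outdir, **sections) -> None:
    """Write the fully resolved configuration next to the outputs."""
    resolved = {}
    for name, obj in sections.items():
        if obj is None:
            continue
        resolved[name] = asdict(obj) if hasattr(obj, "__dataclass_fields__") else obj
    Path(outdir).mkdir(parents=True, exist_ok=True)
    (Path(outdir) / "resolved_config.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True)
    )
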