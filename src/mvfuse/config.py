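"""Configuration schema, validation, and the reproducibility run manifest.

One YAML file with per-stage sections drives the whole pipeline
(generate -> split -> train -> evaluate/ablate -> explain -> quantify);
CLI flags override config values.  Schema violations raise
:class:`ConfigError` naming the offending key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dataset_io import DEFAULT_FRACTIONS
from .multiview_model import ModelConfig
from .synthetic_specimens import GeneratorConfig
from .trainer import TrainConfig


class ConfigError(ValueError):
    """Invalid or missing configuration key."""


_SECTIONS = ("generate", "split", "model", "train", "quantify",
             "stages", "out_dir", "dataset", "seed")


def _build(section: str, cls, payload: dict, required: tuple = ()):
    fields = {f.name for f in dataclasses.fields(cls)}
    for key in payload:
        if key not in fields:
            raise ConfigError(f"unknown key {section}.{key}")
    for key in required:
        if key not in payload:
            raise ConfigError(f"missing required key {section}.{key}")
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in payload.items()}
    try:
        obj = cls(**kwargs)
        if hasattr(obj, "validate"):
            obj.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc
    return obj


@dataclass
class PipelineConfig:
    generate: GeneratorConfig
    model: ModelConfig
    train: TrainConfig
    split_fractions: tuple = DEFAULT_FRACTIONS
    split_seed: int = 0
    split_unit: str = "specimen"
    quantify_tau: float = 0.15
    stages: tuple = ("generate", "split", "train", "evaluate")
    out_dir: str = "runs"
    dataset: str | None = None  # existing dataset dir; skips generate
    seed: int = 42


def load_config(path_or_dict) -> PipelineConfig:
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    for key in raw:
        if key not in _SECTIONS:
            raise ConfigError(f"unknown key {key}")

    gen = _build("generate", GeneratorConfig, raw.get("generate", {}))
    model = _build("model", ModelConfig, raw.get("model", {}),
                   required=("variant",))
    train = _build("train", TrainConfig, raw.get("train", {}))

    split = raw.get("split", {})
    for key in split:
        if key not in ("fractions", "seed", "unit"):
            raise ConfigError(f"unknown key split.{key}")
    quant = raw.get("quantify", {})
    for key in quant:
        if key not in ("tau",):
            raise ConfigError(f"unknown key quantify.{key}")

    return PipelineConfig(
        generate=gen, model=model, train=train,
        split_fractions=tuple(split.get("fractions", DEFAULT_FRACTIONS)),
        split_seed=int(split.get("seed", 0)),
        split_unit=split.get("unit", "specimen"),
        quantify_tau=float(quant.get("tau", 0.15)),
        stages=tuple(raw.get("stages", ("generate", "split", "train", "evaluate"))),
        out_dir=str(raw.get("out_dir", "runs")),
        dataset=raw.get("dataset"),
        seed=int(raw.get("seed", 42)),
    )


# ---------------------------------------------------------------------------
# Reproducibility manifest
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    config_snapshot: dict
    seed: int
    package_version: str
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def record_input(self, name: str, path) -> None:
        p = Path(path)
        if p.is_file():
            self.input_digests[name] = _digest(p)

    def record_output(self, name: str, path) -> None:
        self.outputs[name] = str(path)

    def stamp(self, stage: str) -> None:
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def save(self, path) -> None:
        Path(path).write_text(dump_json(dataclasses.asdict(self)))


def dump_json(obj) -> str:
    """Deterministic JSON: sorted keys, repr-stable floats."""
    return json.dumps(obj, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, tuple)):
        return sorted(o) if isinstance(o, set) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
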