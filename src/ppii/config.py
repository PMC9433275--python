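"""Layered run configuration (defaults < config file < flags), seed fan-out,
and run manifests that make every CLI invocation reproducible."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError

DEFAULTS: dict[str, Any] = {
    "window": 15,
    "kernels": [3, 4, 5],
    "tau": 30.0,
    "mode": "strict",
    "scheme": "4:1",
    "threshold": 0.5,
    "d_model": 32,
    "n_heads": 2,
    "n_layers": 2,
    "d_ff": 64,
    "filters_q": 16,
    "epochs": 12,
    "batch_size": 64,
    "learning_rate": 1e-3,
}


def resolve_config(defaults: Mapping[str, Any],
                   file_path: Optional[str] = None,
                   flags: Optional[Mapping[str, Any]] = None
                   ) -> dict[str, Any]:
    """Merge with precedence flags > file > defaults; unknown keys and type
    mismatches are rejected with the offending key named."""
    resolved = dict(defaults)

    def _apply(source: Mapping[str, Any], origin: str) -> None:
        for key, value in source.items():
            if value is None:
                continue
            if key not in resolved:
                raise ConfigError(f"unknown configuration key {key!r} "
                                  f"(from {origin})")
            expected = resolved[key]
            if expected is not None and value is not None:
                if isinstance(expected, bool) != isinstance(value, bool):
                    raise ConfigError(
                        f"configuration key {key!r}: expected "
                        f"{type(expected).__name__}, got "
                        f"{type(value).__name__}")
                if isinstance(expected, (int, float)) \
                        and not isinstance(expected, bool):
                    if not isinstance(value, (int, float)) \
                            or isinstance(value, bool):
                        raise ConfigError(
                            f"configuration key {key!r}: expected a number, "
                            f"got {type(value).__name__}")
                elif not isinstance(value, type(expected)):
                    raise ConfigError(
                        f"configuration key {key!r}: expected "
                        f"{type(expected).__name__}, got "
                        f"{type(value).__name__}")
            resolved[key] = value

    if file_path is not None:
        path = Path(file_path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            loaded = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        _apply(loaded, str(path))
    if flags:
        _apply(flags, "command line")
    return resolved


def child_seed(seed: int, name: str) -> int:
    """Deterministic named sub-seed below 2^31, so subsystems (split,
    undersample, init, batching) are independently reproducible."""
    digest = hashlib.sha256(name.encode()).digest()
    salt = int.from_bytes(digest[:4], "big")
    mixed = np.random.SeedSequence([seed, salt]).generate_state(1)[0]
    return int(mixed % (2 ** 31))


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    subcommand: str
    config: dict
    seed: Optional[int] = None
    inputs: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def __post_init__(self):
        if not self.started:
            self.started = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def write(self, path) -> None:
        self.finished = datetime.datetime.now(
            datetime.timezone.utc).isoformat()
        payload = {
            "subcommand": self.subcommand,
            "config": self.config,
            "seed": self.seed,
            "inputs": self.inputs,
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))
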