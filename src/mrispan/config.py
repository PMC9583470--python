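"""Run configuration: schema-validated flat key/value settings.

Precedence is CLI flag > config file > built-in default.  Every run
writes its resolved configuration next to its outputs together with a
structured log line (seed, config hash, version), so any artifact can be
reproduced from what sits beside it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .mrc import DEFAULT_QUESTION

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Unknown key, bad type, or unreadable config file."""


_ENCODER_KEYS = {
    "encoder_kind": "self_attention",
    "hidden_dim": 64,
    "n_layers": 2,
    "n_heads": 2,
    "max_length": 400,
    "dropout": 0.1,
}

_TRAINING_KEYS = {
    "learning_rate": 3e-5,
    "batch_size": 32,
    "epochs": 5,
    "optimizer": "adam",
    "grad_clip": 5.0,
    "lr_schedule": "constant",
    "warmup_fraction": 0.1,
}

#: per-command schemas: key -> default
SCHEMAS: dict[str, dict[str, Any]] = {
    "generate": {
        "n_reports": 100,
        "empty_fraction": 0.1,
        "mean_dwi_mentions": 2.0,
        "mean_other_mentions": 8.0,
        "target_mean_length": 170,
        "max_length": 525,
        "shared_part_rate": 0.3,
        "broken_writing_rate": 0.05,
        "seed": 0,
    },
    "train-mrc": {"question": DEFAULT_QUESTION, "seed": 0,
                  "positive_weight": 1.0,
                  **_ENCODER_KEYS, **_TRAINING_KEYS},
    "train-ner": {"seed": 0, **_ENCODER_KEYS, **_TRAINING_KEYS},
    "train-fet": {"seed": 0, "context_window": None,
                  **_ENCODER_KEYS,
                  **_TRAINING_KEYS},
    "predict": {"method": "mrc", "threshold": 0.5, "question": None},
    "evaluate": {"label": "DWI_HIGH"},
}


def resolve_config(command: str, file_path: str | None = None,
                   overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge defaults, config file and CLI overrides; reject unknown keys."""
    if command not in SCHEMAS:
        raise ConfigError(f"unknown command {command!r}")
    resolved = dict(SCHEMAS[command])
    for source_name, source in (("config file", _load_file(file_path)),
                                ("command line", dict(overrides or {}))):
        for key, value in source.items():
            if value is None and key not in resolved:
                continue
            if key not in resolved:
                raise ConfigError(f"unknown key {key!r} from {source_name} "
                                  f"for command {command!r}")
            if value is not None:
                resolved[key] = value
    return resolved


def _load_file(path: str | None) -> dict[str, Any]:
    if path is None:
        return {}
    try:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except (OSError, yaml.YAMLError) as err:
        raise ConfigError(f"cannot read config file {path}: {err}") from err
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError("config file must hold a flat mapping")
    return data


def config_hash(resolved: Mapping[str, Any]) -> str:
    payload = json.dumps(resolved, sort_keys=True, ensure_ascii=False)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def write_run_record(out_dir, command: str, resolved: Mapping[str, Any]) -> Path:
    """Persist the resolved config and append a plain-text run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "version": __version__,
        "config_hash": config_hash(resolved),
        "config": dict(resolved),
    }
    path = out_dir / f"{command}.config.json"
    path.write_text(json.dumps(record, indent=2, ensure_ascii=False),
                    encoding="utf-8")
    log_line = (f"command={command} version={__version__} "
                f"hash={record['config_hash']} seed={resolved.get('seed')} "
                f"question={resolved.get('question')!r}")
    with (out_dir / "run.log").open("a", encoding="utf-8") as fh:
        fh.write(log_line + "\n")
    logger.info(log_line)
    return path
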