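"""Declarative configuration: one YAML file carries every tunable
parameter (task composition, simulator slopes, filter behavior) plus
the global seed."""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Optional, Union

import yaml

from .simulate import SimConfig

log = logging.getLogger("taskphenotype")


def setup_logging(level: int = logging.INFO) -> None:
    """Leveled logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


def load_config(path: Optional[Union[str, Path]] = None) -> SimConfig:
    """Load a nested key-value YAML config; defaults when no file is
    given.  Unknown keys are rejected by the pydantic model."""
    if path is None:
        return SimConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return SimConfig(**raw)


def save_config(config: SimConfig, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
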