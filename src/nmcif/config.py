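"""YAML configuration loading with section-wise defaults."""

from __future__ import annotations

from pathlib import Path

import yaml

from .evaluation import DEFAULT_CONFIG, _deep_merge

__all__ = ["load_config", "DEFAULT_CONFIG"]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config file and merge it over the package defaults.

    Sections mirror the module settings (``kernel.sigma``, ``fixedpoint.omega``,
    ``observer.n_hidden``, ``scenario.*``, ``contamination.*`` ...).  ``overrides``
    are applied last (CLI flags beat the file, which beats the defaults).
    """
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg
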