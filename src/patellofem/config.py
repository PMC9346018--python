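"""Run-configuration loading (YAML) with study defaults."""

from __future__ import annotations

from pathlib import Path

import yaml

from .study import DEFAULT_STUDY_CONFIG, _merge


def default_config() -> dict:
    return _merge(DEFAULT_STUDY_CONFIG, None)


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML run configuration over the study defaults."""
    if path is None:
        return default_config()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: run configuration must be a mapping")
    return _merge(DEFAULT_STUDY_CONFIG, data)
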