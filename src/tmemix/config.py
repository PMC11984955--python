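"""Plain-text run configuration (YAML, one namespace per module).

Example::

    ode:
      preset: inefficient-T
      t_end: 100
    spatial:
      scenario: immune-excluded
      n: 128
      length: 300.0
      params:
        tau_t: 2.5

Flag overrides beat config values, which beat built-in defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ValueError(f"config parse error in {path}{line}: {exc}") from None
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def section(config: dict, name: str) -> dict:
    sec = config.get(name, {})
    if not isinstance(sec, dict):
        raise ValueError(f"config section {name!r} must be a mapping")
    return sec
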