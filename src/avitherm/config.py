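"""Flat key-value configuration files.

Run configuration is stored as namespaced ``section.key = value`` lines
(``#`` comments allowed), e.g.::

    generator.n_individuals = 24
    generator.true_tlc = 17.7
    generator.male.wing_mean = 78.0
    trace.flow_rate = 1000
    analysis.grid_step = 0.05
    seed = 1

Types are coerced from the dataclass field defaults; tuples are written
as comma-separated lists.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

from .synthetic import GeneratorConfig, TraceConfig

__all__ = ["flatten_config", "unflatten_config", "write_config",
           "read_config", "load_configs"]


def flatten_config(obj: Any, prefix: str = "") -> dict[str, str]:
    """Flatten a (possibly nested) dataclass into namespaced keys."""
    out: dict[str, str] = {}
    for f in dataclasses.fields(obj):
        value = getattr(obj, f.name)
        key = f"{prefix}{f.name}"
        if dataclasses.is_dataclass(value):
            out.update(flatten_config(value, prefix=f"{key}."))
        elif isinstance(value, (tuple, list)):
            out[key] = ",".join(str(v) for v in value)
        else:
            out[key] = str(value)
    return out


def _coerce(text: str, template: Any) -> Any:
    if isinstance(template, bool):
        return text.strip().lower() in ("1", "true", "yes")
    if isinstance(template, int) and not isinstance(template, bool):
        return int(text)
    if isinstance(template, float):
        return float(text)
    if isinstance(template, (tuple, list)):
        return tuple(float(v) for v in text.split(","))
    return text.strip()


def unflatten_config(flat: dict[str, str], cls: type, prefix: str = "") -> Any:
    """Rebuild a dataclass from namespaced keys, defaulting missing ones."""
    return _unflatten_from(cls(), flat, prefix)


def _unflatten_from(template: Any, flat: dict[str, str], prefix: str) -> Any:
    overrides = {}
    for f in dataclasses.fields(template):
        key = f"{prefix}{f.name}"
        current = getattr(template, f.name)
        if dataclasses.is_dataclass(current):
            sub_prefix = f"{key}."
            if any(k.startswith(sub_prefix) for k in flat):
                overrides[f.name] = _unflatten_from(current, flat, sub_prefix)
        elif key in flat:
            overrides[f.name] = _coerce(flat[key], current)
    return dataclasses.replace(template, **overrides)


def write_config(flat: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(flat):
            fh.write(f"{key} = {flat[key]}\n")


def read_config(path: str | Path) -> dict[str, str]:
    flat: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        flat[key.strip()] = value.strip()
    return flat


def load_configs(path: str | Path | None,
                 ) -> tuple[GeneratorConfig, TraceConfig, dict[str, str]]:
    """Load generator and trace configs (and the raw map) from a file.

    ``None`` returns pure defaults.  Keys outside the ``generator.`` and
    ``trace.`` namespaces are returned untouched in the raw map for the
    caller (e.g. ``analysis.*`` switches, ``seed``).
    """
    flat = read_config(path) if path is not None else {}
    gen = unflatten_config(flat, GeneratorConfig, prefix="generator.")
    trace = unflatten_config(flat, TraceConfig, prefix="trace.")
    return gen, trace, flat
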