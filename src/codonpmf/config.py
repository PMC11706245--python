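"""Structured plain-text (YAML) run configuration with a strict schema.

Unknown keys are errors, not warnings: a typo in a run file must not
silently fall back to a default.  The schema is versioned; version 1 is the
only one defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

_SCHEMA_VERSION = 1

_TOP_KEYS = {
    "version", "presets", "trials", "steps", "seed", "grid", "dynamics",
    "abf", "checkpoints", "window", "preset_overrides", "reference",
    "temperature", "jacobian",
}
_GRID_KEYS = {"lower", "upper", "width"}
_DYN_KEYS = {"timestep", "friction", "mass", "boundary_stiffness", "stride"}
_ABF_KEYS = {"n_full", "burn_in_fraction"}
_WINDOW_KEYS = {"center", "half_width"}


@dataclass(frozen=True)
class RunConfig:
    """Validated end-to-end pipeline configuration."""

    presets: tuple[str, ...]
    trials: int = 5
    steps: int = 2_000_000
    seed: int = 1
    grid: Mapping[str, float] = field(default_factory=lambda: {"lower": 4.0, "upper": 9.0, "width": 0.5})
    dynamics: Mapping[str, float] = field(default_factory=dict)
    abf: Mapping[str, float] = field(default_factory=lambda: {"n_full": 200, "burn_in_fraction": 0.05})
    checkpoints: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    window: Mapping[str, Any] = field(default_factory=lambda: {"center": [4.5, 4.5, 4.5], "half_width": 0.25})
    preset_overrides: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    reference: str = "AUG"
    temperature: float = 310.0
    jacobian: bool = False

    def __post_init__(self) -> None:
        if not self.presets:
            raise ValueError("config must name at least one preset")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def _reject_unknown(section: str, given: Mapping, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )


def parse_config(raw: Mapping[str, Any]) -> RunConfig:
    if not isinstance(raw, Mapping):
        raise ValueError("config root must be a mapping")
    _reject_unknown("<root>", raw, _TOP_KEYS)
    version = raw.get("version", _SCHEMA_VERSION)
    if version != _SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    for sec, allowed in (("grid", _GRID_KEYS), ("dynamics", _DYN_KEYS),
                         ("abf", _ABF_KEYS), ("window", _WINDOW_KEYS)):
        if sec in raw:
            _reject_unknown(sec, raw[sec], allowed)
    kwargs: dict[str, Any] = {k: v for k, v in raw.items() if k != "version"}
    kwargs["presets"] = tuple(kwargs["presets"])
    if "checkpoints" in kwargs:
        kwargs["checkpoints"] = tuple(float(x) for x in kwargs["checkpoints"])
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw or {})
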