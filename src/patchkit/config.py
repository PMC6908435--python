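"""Run configuration: YAML with one section per pipeline stage.

All tunable constants live here with their defaults; a config file only
needs the keys it overrides. Unknown keys raise, so typos surface early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "DEFAULTS"]

DEFAULTS: dict[str, dict] = {
    "simulate": {
        "n_tracks": 50,
        "preset": "fission-like",  # or "budding-like"
        "between_event_cv": 0.05,
        "roi_size": 5000.0,
    },
    "io": {
        "nm_per_pixel": 65.0,
        "storm_nm_per_pixel": 160.0,
        "frame_interval": 1.0 / 9.0,
    },
    "dynamics": {
        "mode": "inflection",
        "smooth_window": 3,
        "k": 2.0,
        "m": 3,
        "n_min": 3,
        "min_separation": 325.0,
        "lifetime_frac": 0.1,
        # marker -> alignment mode; actin markers align at half-max,
        # coat/NPF markers at the motion inflection
        "marker_modes": {
            "Abp1": "half_max",
            "Fim1": "half_max",
            "Sac6": "half_max",
        },
    },
    "counting": {
        "anchors": {"scSla1": 168.0, "scLas17": 102.0, "scMyo5": 199.0},
        "brightness": {"GFP": 1.0, "mEGFP": 1.14, "sfGFP": 1.0, "EGFP": 1.0},
        "consistency_tolerance": 0.20,
    },
    "storm": {
        "y_threshold": 0.01,
        "auto_rotate": True,
    },
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    merged = dict(defaults)
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigurationError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and key not in ("marker_modes", "anchors", "brightness"):
            if not isinstance(value, dict):
                raise ConfigurationError(f"{where} must be a mapping")
            merged[key] = _merge(defaults[key], value, where)
        else:
            merged[key] = value
    return merged


@dataclass
class RunConfig:
    """Validated, fully defaulted configuration for a pipeline run."""

    sections: dict[str, dict] = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULTS.items()})
    source: str | None = None

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        if path is None:
            return cls()
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config root must be a mapping of sections")
        return cls(sections=_merge(DEFAULTS, raw), source=str(path))

    def __getitem__(self, section: str) -> dict:
        try:
            return self.sections[section]
        except KeyError:
            raise ConfigurationError(f"unknown config section {section!r}") from None
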