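"""Run configuration shared by the CLI and batch entry points.

Defaults reproduce the published numbers: the DCCT conversion with the
printed inverse intercept and the rounded MPG-space constants.  The exact
modes exist for algebraic self-consistency work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["RunConfig", "load_config"]

_MODES = ("paper", "exact")
_FORMATS = ("csv", "json")


@dataclass(frozen=True)
class RunConfig:
    model: str = "DCCT"
    intercept_mode: str = "paper"
    constant_mode: str = "paper"
    rounding: str = "half-away"  # display rounding convention; raw values never round
    hbx_mask_lo: float = 0.0  # error-grid plausibility envelope, % HbA1c
    hbx_mask_hi: float = 20.0
    output_format: str = "csv"
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        from .conversion import MODELS

        if self.model not in MODELS:
            raise ValueError(f"unknown conversion model {self.model!r}; choose from {sorted(MODELS)}")
        if self.intercept_mode not in _MODES or self.constant_mode not in _MODES:
            raise ValueError(f"modes must be one of {_MODES}")
        if self.output_format not in _FORMATS:
            raise ValueError(f"output format must be one of {_FORMATS}")
        if not self.hbx_mask_lo < self.hbx_mask_hi:
            raise ValueError("mask bounds must satisfy lo < hi")

    @property
    def conversion_model(self):
        from .conversion import MODELS

        return MODELS[self.model]

    @property
    def hbx_bounds(self) -> tuple[float, float]:
        return (self.hbx_mask_lo, self.hbx_mask_hi)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        numeric = {"hbx_mask_lo", "hbx_mask_hi"}
        coerced = {
            k: (float(v) if k in numeric else str(v)) for k, v in mapping.items()
        }
        return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load a config file: JSON object, or simple ``key=value`` lines."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return RunConfig.from_mapping(json.loads(text))
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        mapping[key.strip()] = value.strip()
    return RunConfig.from_mapping(mapping)
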