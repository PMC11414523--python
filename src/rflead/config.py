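"""Flat key-value configuration files for materials, wire geometry and frequency.

The config is YAML with flat scalar keys, e.g.::

    relative_permittivity: 80
    conductivity: 0.47
    conductor_radius_a_mm: 0.390
    insulation_outer_radius_b_mm: 0.625
    insulation_relative_permittivity: 2.3
    field_strength_T: 3.0        # or frequency_Hz: 127.74e6

Either ``field_strength_T`` or ``frequency_Hz`` must be present; an explicit
frequency takes precedence over the field strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .media import MaterialProperties, WireGeometry, larmor_frequency

REQUIRED_KEYS = (
    "relative_permittivity",
    "conductivity",
    "conductor_radius_a_mm",
    "insulation_outer_radius_b_mm",
    "insulation_relative_permittivity",
)


class ConfigError(ValueError):
    """Missing or malformed configuration keys."""


@dataclass(frozen=True)
class StudyConfig:
    """Resolved configuration: medium, wire geometry, and frequency in Hz."""

    medium: MaterialProperties
    geometry: WireGeometry
    frequency: float

    @property
    def frequency_mhz(self) -> float:
        return self.frequency / 1e6


def load_config(path: str | Path) -> StudyConfig:
    """Parse a flat YAML config file into a :class:`StudyConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a flat key-value mapping")
    missing = [k for k in REQUIRED_KEYS if k not in raw]
    if "frequency_Hz" not in raw and "field_strength_T" not in raw:
        missing.append("field_strength_T or frequency_Hz")
    if missing:
        raise ConfigError(f"config {path} is missing keys: {', '.join(missing)}")

    try:
        medium = MaterialProperties(
            relative_permittivity=float(raw["relative_permittivity"]),
            conductivity=float(raw["conductivity"]),
            relative_permeability=float(raw.get("relative_permeability", 1.0)),
        )
        geometry = WireGeometry(
            conductor_radius_a=float(raw["conductor_radius_a_mm"]) * 1e-3,
            insulation_outer_radius_b=float(raw["insulation_outer_radius_b_mm"]) * 1e-3,
            insulation_relative_permittivity=float(raw["insulation_relative_permittivity"]),
        )
        if "frequency_Hz" in raw:
            frequency = float(raw["frequency_Hz"])
            if frequency <= 0:
                raise ValueError("frequency_Hz must be > 0")
        else:
            frequency = larmor_frequency(float(raw["field_strength_T"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config {path}: {exc}") from exc
    return StudyConfig(medium=medium, geometry=geometry, frequency=frequency)
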