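"""Shared fixtures: the published phantom-study configuration.

The reference conditions are an ASTM-style gelled-saline phantom
(relative permittivity 80, conductivity 0.47 S/m) hosting a straight
insulated wire (conductor radius 0.390 mm, insulation outer radius
0.625 mm, insulation relative permittivity 2.3), scanned at 1.5 T
(63.87 MHz) and 3 T (127.74 MHz).
"""

import numpy as np
import pytest

from rflead import (
    MaterialProperties,
    WireGeometry,
    insulator_wavenumber,
    king_wavenumber,
    larmor_frequency,
    medium_wavenumber,
)

WIRE_LENGTHS_CM = [
    2.38, 10.38, 16.38, 20.38, 21.38, 22.38, 26.38, 29.38,
    32.78, 35.78, 39.78, 40.78, 41.78, 25.78, 50.78,
]


@pytest.fixture(scope="session")
def gel() -> MaterialProperties:
    return MaterialProperties(relative_permittivity=80.0, conductivity=0.47)


@pytest.fixture(scope="session")
def geometry() -> WireGeometry:
    return WireGeometry(
        conductor_radius_a=0.390e-3,
        insulation_outer_radius_b=0.625e-3,
        insulation_relative_permittivity=2.3,
    )


@pytest.fixture(scope="session")
def f15() -> float:
    return larmor_frequency(1.5)


@pytest.fixture(scope="session")
def f30() -> float:
    return larmor_frequency(3.0)


def _king(gel, geometry, f):
    kt = medium_wavenumber(gel, f)
    ki = insulator_wavenumber(geometry.insulation_relative_permittivity, f)
    return king_wavenumber(ki, kt, geometry)


@pytest.fixture(scope="session")
def king15(gel, geometry, f15):
    return _king(gel, geometry, f15)


@pytest.fixture(scope="session")
def king30(gel, geometry, f30):
    return _king(gel, geometry, f30)


@pytest.fixture(scope="session")
def wire_lengths_m() -> np.ndarray:
    """Lengths of the 15 study wires, meters, sorted ascending."""
    return np.sort(np.asarray(WIRE_LENGTHS_CM)) / 100.0


@pytest.fixture()
def study_config(tmp_path):
    """Write the reference phantom/wire config to a temp YAML file."""

    def _write(field_strength_T=3.0, **overrides):
        entries = {
            "relative_permittivity": 80,
            "conductivity": 0.47,
            "conductor_radius_a_mm": 0.390,
            "insulation_outer_radius_b_mm": 0.625,
            "insulation_relative_permittivity": 2.3,
            "field_strength_T": field_strength_T,
        }
        entries.update(overrides)
        entries = {k: v for k, v in entries.items() if v is not None}
        path = tmp_path / "config.yaml"
        path.write_text("\n".join(f"{k}: {v}" for k, v in entries.items()) + "\n")
        return path

    return _write
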