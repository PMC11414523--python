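"""Wire paths, complex vector E-fields, and synthetic study fixtures.

Coordinates are right-handed with z along the scanner bore axis and all
lengths in meters.  A :class:`WirePath` is an ordered polyline whose first
point is the lead tip; arc length l is measured from there.  An
:class:`EFieldGrid` stores a complex 3-vector field on a regular grid and
interpolates trilinearly (each real/imaginary component independently, no
extrapolation).

The synthetic body-coil field is an analytic surrogate for a full-wave coil
simulation: a dominant Ez whose magnitude grows linearly with lateral
distance |x| from the midline, tapers smoothly along z, and carries a phase
varying linearly in z; small Ex/Ey components are included.  It exists so
that every downstream stage (projection, line integral, fitting) is testable
without external field data.

The synthetic measurement generator draws per-wire transmit-gain values and
Gaussian temperature noise around a scaled model heating curve, emulating a
multi-wire phantom heating study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fitting import TemperatureMeasurement
from .transfer import ModelKind, TransferModel, delta_T_sem, delta_T_tlm


@dataclass(frozen=True)
class WirePath:
    """Ordered 3-D polyline for an implanted wire; points[0] is the lead tip."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("points must be an (N>=2, 3) array")
        seg = np.diff(pts, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0):
            raise ValueError("consecutive path points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def segments(self) -> np.ndarray:
        """Segment vectors dl, shape (N-1, 3)."""
        return np.diff(self.points, axis=0)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segments, axis=1)

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length from the lead tip at each point, shape (N,)."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.points[:-1] + self.points[1:])

    @property
    def midpoint_arclengths(self) -> np.ndarray:
        arc = self.arc_lengths
        return 0.5 * (arc[:-1] + arc[1:])

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.points, columns=["x_m", "y_m", "z_m"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WirePath":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df[["x_m", "y_m", "z_m"]].to_numpy())


def straight_path(
    start: Sequence[float], direction: Sequence[float], length: float, step: float
) -> WirePath:
    """Evenly sampled straight wire from ``start`` along ``direction``."""
    if length <= 0 or step <= 0:
        raise ValueError("length and step must be > 0")
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction vector must be nonzero")
    unit = direction / norm
    n_seg = max(1, round(length / step))
    arc = np.linspace(0.0, length, n_seg + 1)
    return WirePath(np.asarray(start, dtype=float)[None, :] + arc[:, None] * unit[None, :])


class ConstantField:
    """Spatially uniform complex E-field vector."""

    def __init__(self, value: Sequence[complex]):
        v = np.asarray(value, dtype=complex)
        if v.shape != (3,):
            raise ValueError("field value must be a complex 3-vector")
        self.value = v

    def sample(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return np.broadcast_to(self.value, (points.shape[0], 3)).copy()


@dataclass(frozen=True)
class EFieldGrid:
    """Complex 3-vector field sampled on a regular grid.

    ``values`` has shape (len(x), len(y), len(z), 3); axes must be strictly
    increasing.  Queries outside the grid raise, naming the point.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        z = np.asarray(self.z, dtype=float)
        values = np.asarray(self.values, dtype=complex)
        for name, axis in (("x", x), ("y", y), ("z", z)):
            if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
                raise ValueError(f"axis {name} must be 1-D, length >= 2, strictly increasing")
        if values.shape != (x.size, y.size, z.size, 3):
            raise ValueError(
                f"values shape {values.shape} inconsistent with axes "
                f"({x.size}, {y.size}, {z.size}, 3)"
            )
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "values", values)

    def _interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.x, self.y, self.z), self.values, method="linear", bounds_error=True
        )

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the complex field at (N, 3) points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.array([self.x[0], self.y[0], self.z[0]])
        hi = np.array([self.x[-1], self.y[-1], self.z[-1]])
        outside = np.any((points < lo) | (points > hi), axis=1)
        if np.any(outside):
            bad = points[np.argmax(outside)]
            raise ValueError(f"point {tuple(bad)} is outside the field grid domain")
        return self._interpolator()(points)

    # -- delimited-text round trip ------------------------------------------
    # One node per line, x-fastest ordering, columns:
    # x_m y_m z_m ReEx ImEx ReEy ImEy ReEz ImEz

    def to_text(self, path: str | Path) -> None:
        nx, ny, nz = self.x.size, self.y.size, self.z.size
        X, Y, Z = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        # x-fastest: index order (z, y, x) when flattened C-style
        order = np.transpose(self.values, (2, 1, 0, 3)).reshape(-1, 3)
        coords = np.stack(
            [
                np.transpose(X, (2, 1, 0)).ravel(),
                np.transpose(Y, (2, 1, 0)).ravel(),
                np.transpose(Z, (2, 1, 0)).ravel(),
            ],
            axis=1,
        )
        table = np.column_stack(
            [coords]
            + [comp for j in range(3) for comp in (order[:, j].real, order[:, j].imag)]
        )
        header = "x_m y_m z_m ReEx ImEx ReEy ImEy ReEz ImEz"
        np.savetxt(path, table, header=header, fmt="%.9e")

    @classmethod
    def from_text(cls, path: str | Path) -> "EFieldGrid":
        table = np.loadtxt(path)
        if table.ndim != 2 or table.shape[1] != 9:
            raise ValueError(f"{path}: expected 9 columns (x y z + 3 complex components)")
        x = np.unique(table[:, 0])
        y = np.unique(table[:, 1])
        z = np.unique(table[:, 2])
        if x.size * y.size * z.size != table.shape[0]:
            raise ValueError(f"{path}: nodes do not form a complete regular grid")
        complex_vals = table[:, 3::2] + 1j * table[:, 4::2]  # (N, 3)
        values = np.transpose(
            complex_vals.reshape(z.size, y.size, x.size, 3), (2, 1, 0, 3)
        )
        return cls(x, y, z, values)


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Parameters of the analytic body-coil field surrogate.

    ``amplitude``: peak |Ez| in V/m; ``lateral_scale``: x-distance over which
    |Ez| ramps to its peak; ``longitudinal_period``: spatial period of the
    linear z-phase; ``half_widths``: (x, y, z) phantom half-widths used for
    the smooth z-taper.
    """

    amplitude: float = 100.0
    lateral_scale: float = 0.21
    longitudinal_period: float = 0.65
    half_widths: tuple[float, float, float] = (0.21, 0.15, 0.325)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.lateral_scale <= 0 or self.longitudinal_period <= 0:
            raise ValueError("scales must be > 0")
        if any(h <= 0 for h in self.half_widths):
            raise ValueError("half_widths must be > 0")


def synthetic_body_coil_field(
    spec: SyntheticFieldSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> EFieldGrid:
    """Analytic stand-in for a simulated body-coil E-field on a regular grid.

    |Ez| = amplitude * (0.1 + 0.9*min(|x|/lateral_scale, 1)) * cos(pi*z/(2*zhw)),
    with phase exp(2*pi*i*z/period); Ex and Ey are set to 5% of the peak with
    the same envelope, keeping the transverse components small relative to Ez
    as in body-coil transmission.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    zhw = spec.half_widths[2]
    lateral = 0.1 + 0.9 * np.minimum(np.abs(X) / spec.lateral_scale, 1.0)
    taper = np.cos(np.clip(np.pi * Z / (2.0 * zhw), -np.pi / 2, np.pi / 2))
    phase = np.exp(2j * np.pi * Z / spec.longitudinal_period)
    Ez = spec.amplitude * lateral * taper * phase
    transverse = 0.05 * spec.amplitude * lateral * taper * phase
    values = np.stack([transverse, transverse, Ez], axis=-1)
    return EFieldGrid(x, y, z, values)


def tangential_component(field, path: WirePath) -> np.ndarray:
    """Complex tangential field Et = E . dl/|dl| at each segment midpoint."""
    E = field.sample(path.midpoints)
    units = path.segments / path.segment_lengths[:, None]
    return np.einsum("ij,ij->i", E, units.astype(complex))


def synthetic_measurements(
    model: TransferModel,
    scale: float,
    lengths: Sequence[float],
    noise_sd: float,
    tg_spread: float,
    seed: int | np.random.Generator,
    e_abs: float = 1.0,
    tg_ref: float = 120.0,
) -> list[TemperatureMeasurement]:
    """Generate a synthetic multi-wire heating data set.

    For each wire length d the noiseless rise is ``scale * delta_T_model(d)``;
    the wire's transmit gain is drawn as TG_j ~ Normal(tg_ref, tg_spread),
    which scales the delivered RF power (and the recorded rise) by
    10^(-(TG_j - tg_ref)/100), and Gaussian(0, noise_sd) measurement noise is
    added.  Applying the TG correction with ``tg_ref`` recovers the
    uncorrupted mean, so generate -> correct -> fit round-trips exactly in
    the noiseless limit.  Error-component fields are filled consistently
    (probe_difference and baseline_sd proportional to noise_sd, tg_aps_sd =
    tg_spread).
    """
    if noise_sd < 0 or tg_spread < 0:
        raise ValueError("noise_sd and tg_spread must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.asarray(lengths, dtype=float)
    if model.kind is ModelKind.SEM:
        clean = scale * np.asarray(delta_T_sem(e_abs, model.wavenumber, lengths))
    else:
        clean = scale * np.asarray(delta_T_tlm(e_abs, model.wavenumber, model.gamma, lengths))
    tg = tg_ref + tg_spread * rng.standard_normal(lengths.size)
    recorded = clean * 10.0 ** (-(tg - tg_ref) / 100.0) + noise_sd * rng.standard_normal(
        lengths.size
    )
    return [
        TemperatureMeasurement(
            wire_length=float(d),
            measured_delta_T=float(dt),
            tg_aps=float(t),
            tg_aps_sd=tg_spread,
            probe_difference=0.5 * noise_sd,
            baseline_sd=0.5 * noise_sd,
        )
        for d, dt, t in zip(lengths, recorded, tg)
    ]
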