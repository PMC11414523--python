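"""Resonant lead length: transcendental roots and numerical maximization.

The lead length that maximizes tip heating follows from d(delta_T)/dd = 0.
With the dimensionless variables u = -kI/kR (loss ratio) and g = kR*d/pi
(length in half-wavelengths), the stationarity condition becomes a
transcendental equation in g whose smallest positive root lies in [1/2, 1]:

* simple exponential model:        -u*exp(-pi*u*g) + u*cos(pi*g) + sin(pi*g) = 0
* transmission line, Gamma = 1:     tan(pi*g) + u*tanh(pi*u*g) = 0
  (equivalently kR*tan(kR*d) + kI*tanh(kI*d) = 0; the root's argument kR*d
  lies in the second quadrant)

so the resonant length d_res = (lambda/2) * g(u) is always bounded between a
quarter and half wavelength in the conductor.  g(0) = 1 exactly and g
decreases monotonically to 1/2 as u -> infinity.  For a general reflection
coefficient the closed-form delta_T is maximized numerically instead.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .media import MaterialProperties, WireGeometry, insulator_wavenumber, king_wavenumber, medium_wavenumber
from .transfer import ModelKind, TransferModel, delta_T_sem, delta_T_tlm

#: Above this loss ratio the root is taken at its asymptote g = 1/2.
_U_ASYMPTOTIC = 1e6
#: Root bracket: g = 1/2 is the infimum, never itself a root for finite u.
_G_LO = 0.5 + 1e-12
_ROOT_XTOL = 1e-14


def _check_u(u: float) -> float:
    u = float(u)
    if u < 0 or math.isnan(u):
        raise ValueError(f"loss ratio u must be >= 0, got {u}")
    return u


def sem_resonance_residual(g, u: float):
    """LHS of the simple-exponential resonance equation; zero at the root."""
    g = np.asarray(g, dtype=float)
    out = -u * np.exp(-math.pi * u * g) + u * np.cos(math.pi * g) + np.sin(math.pi * g)
    return out if out.ndim else float(out)


def tlm_open_resonance_residual(g, u: float):
    """LHS of the Gamma=1 transmission-line resonance equation (in g-form)."""
    g = np.asarray(g, dtype=float)
    out = np.tan(math.pi * g) + u * np.tanh(math.pi * u * g)
    return out if out.ndim else float(out)


def g_sem(u: float) -> float:
    """Resonant length in half-wavelengths for the simple exponential model.

    Smallest positive root of -u*e^(-pi*u*g) + u*cos(pi*g) + sin(pi*g) = 0;
    g(0) = 1, decreasing in u with asymptote 1/2.
    """
    u = _check_u(u)
    if u == 0:
        return 1.0
    if u > _U_ASYMPTOTIC or math.isinf(u):
        return 0.5
    return brentq(sem_resonance_residual, _G_LO, 1.0, args=(u,), xtol=_ROOT_XTOL)


def g_tlm_open(u: float) -> float:
    """Resonant length in half-wavelengths for the transmission line model
    with full reflection (Gamma = 1, electrically open capped end).

    Smallest positive root of tan(pi*g) + u*tanh(pi*u*g) = 0 on (1/2, 1].
    """
    u = _check_u(u)
    if u == 0:
        return 1.0
    if u > _U_ASYMPTOTIC or math.isinf(u):
        return 0.5
    return brentq(tlm_open_resonance_residual, _G_LO, 1.0, args=(u,), xtol=_ROOT_XTOL)


def resonant_length(
    model: TransferModel,
    search_range: tuple[float, float] | None = None,
    grid_step: float = 0.5e-3,
) -> float:
    """Lead length (m) that maximizes the closed-form relative delta_T.

    SEM and TLM with Gamma = 1 use the analytic route (lambda/2) * g(u); the
    TLM with a general reflection coefficient maximizes the closed-form
    delta_T on a grid (default 0.5 mm) over ``search_range`` (default
    (0, lambda]) followed by bounded local refinement.
    """
    k = model.wavenumber
    if k.magnitude == 0:
        raise ValueError("unity transfer function (k = 0): delta_T grows monotonically, no resonance")
    if k.kR == 0:
        raise ValueError("kR = 0: wavelength undefined, no resonance")
    half_wavelength = k.wavelength / 2.0
    u = k.loss_ratio
    gamma = model.gamma
    if model.kind is ModelKind.SEM or gamma == 0:
        return half_wavelength * g_sem(u)
    if gamma == 1:
        return half_wavelength * g_tlm_open(u)

    if search_range is None:
        search_range = (grid_step, k.wavelength)
    lo, hi = search_range
    if not (0 <= lo < hi):
        raise ValueError(f"invalid search range {search_range}")
    lo = max(lo, grid_step / 2)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    if grid.size < 2:
        raise ValueError(f"search range {search_range} too narrow for grid step {grid_step}")
    values = delta_T_tlm(1.0, k, gamma, grid)
    i = int(np.argmax(values))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda d: -delta_T_tlm(1.0, k, gamma, float(d)),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def insulation_thickness_sweep(
    geometry: WireGeometry,
    medium: MaterialProperties,
    frequency: float,
    outer_radii: Iterable[float],
    kind: ModelKind = ModelKind.TLM,
    gamma: complex = 1.0,
) -> pd.DataFrame:
    """Resonant length versus insulation outer radius b.

    For each b the insulated-conductor wavenumber is recomputed and the
    resonant length solved for the requested model.  Over the neighborhood of
    the experimental geometry, thicker insulation lowers the loss ratio and
    lengthens the resonance, so d_res increases with b.

    Returns a DataFrame with columns b_m, kR, kI, u, d_res_m.
    """
    kt = medium_wavenumber(medium, frequency)
    ki = insulator_wavenumber(geometry.insulation_relative_permittivity, frequency)
    rows = []
    for b in outer_radii:
        geo_b = WireGeometry(
            conductor_radius_a=geometry.conductor_radius_a,
            insulation_outer_radius_b=float(b),
            insulation_relative_permittivity=geometry.insulation_relative_permittivity,
        )
        k = king_wavenumber(ki, kt, geo_b)
        d_res = resonant_length(TransferModel(kind, k, gamma))
        rows.append(
            {"b_m": float(b), "kR": k.kR, "kI": k.kI, "u": k.loss_ratio, "d_res_m": d_res}
        )
    return pd.DataFrame(rows)


def brute_force_resonant_length(
    model: TransferModel, d_max: float, step: float = 1e-5
) -> float:
    """Grid argmax of the closed-form delta_T; independent check of the
    analytic g(u) route (default grid 0.01 mm)."""
    grid = np.arange(step, d_max + step / 2, step)
    if model.kind is ModelKind.SEM:
        values = delta_T_sem(1.0, model.wavenumber, grid)
    else:
        values = delta_T_tlm(1.0, model.wavenumber, model.gamma, grid)
    return float(grid[int(np.argmax(values))])
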