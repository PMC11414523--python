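"""Transfer functions, lead-tip voltage, and relative temperature rise.

The lead-tip voltage induced by an incident RF electric field is the line
integral of the tangential field along the lead, weighted by a complex
transfer function h(l) with l the arc length measured from the lead tip:

    V = integral_0^d  h(l) * Et(l)  dl,        delta_T  proportional to  |V|^2.

Two transfer-function families are implemented:

* SEM (simple exponential model):  h(l) = exp(-i*k*l), with k the complex
  wavenumber of current propagation along the wire.
* TLM (transmission line model):  the capped proximal (device) end reflects
  the wave with coefficient Gamma, giving

      h(l) = exp(-i*k*l) * (1 - Gamma*exp(-2i*k*(d-l))) / (1 - Gamma*exp(-2i*k*d)),

  which satisfies h(0) = 1 and reduces to the SEM at Gamma = 0.

For a spatially constant field both models admit closed forms for V and
delta_T; for arbitrary fields the integral is evaluated numerically along a
discretized wire path.  All delta_T values are relative (arbitrary units, the
overall scale is a free parameter fitted elsewhere).
"""

from __future__ import annotations

import cmath
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Protocol

import numpy as np

from .media import SingularDenominatorError, Wavenumber

if TYPE_CHECKING:  # pragma: no cover
    from .efield import WirePath

#: Denominator magnitude below which the TLM is treated as at a resonant pole.
_SINGULAR_TOL = 1e-14


class ModelKind(str, enum.Enum):
    SEM = "sem"
    TLM = "tlm"


@dataclass(frozen=True)
class TransferModel:
    """A transfer-function family plus the parameters that fix it.

    ``gamma`` (the reflection coefficient of the capped end, |gamma| <= 1) is
    only meaningful for the TLM; the SEM ignores it.  ``lead_length`` is the
    total lead length d; for the TLM it is required context wherever a
    concrete lead is evaluated (the TLM transfer function depends on d).
    """

    kind: ModelKind
    wavenumber: Wavenumber
    gamma: complex = 1.0
    lead_length: float | None = None

    def __post_init__(self) -> None:
        if abs(self.gamma) > 1 + 1e-12:
            raise ValueError(f"|gamma| must be <= 1 for a passive termination, got {self.gamma}")
        if self.lead_length is not None and not self.lead_length > 0:
            raise ValueError("lead_length must be > 0")

    def with_length(self, d: float) -> "TransferModel":
        return TransferModel(self.kind, self.wavenumber, self.gamma, d)

    def transfer(self, l, *, proximal_form: bool = False):
        """Evaluate h(l); l may be a scalar or array of arc lengths from the tip."""
        if self.kind is ModelKind.SEM:
            return sem_transfer(self.wavenumber, l)
        if self.lead_length is None:
            raise ValueError("TLM evaluation requires lead_length to be set")
        if proximal_form:
            lp = self.lead_length - np.asarray(l, dtype=float)
            return tlm_transfer_proximal(self.wavenumber, self.gamma, lp, self.lead_length)
        return tlm_transfer(self.wavenumber, self.gamma, l, self.lead_length)

    def describe(self) -> str:
        if self.kind is ModelKind.SEM:
            return "sem"
        g = self.gamma
        return f"tlm(gamma={g.real:g})" if g.imag == 0 else f"tlm(gamma={g:g})"


@dataclass(frozen=True)
class HeatingCurve:
    """Relative temperature rise versus lead length.

    ``lengths`` must be strictly increasing (meters); ``relative_delta_T`` is
    non-negative and in arbitrary units (the proportionality constant between
    |V|^2 and degrees is not fixed here).
    """

    lengths: np.ndarray
    relative_delta_T: np.ndarray
    model: str = ""
    field_description: str = "constant"

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        dt = np.asarray(self.relative_delta_T, dtype=float)
        if lengths.shape != dt.shape or lengths.ndim != 1:
            raise ValueError("lengths and relative_delta_T must be 1-D arrays of equal shape")
        if lengths.size >= 2 and not np.all(np.diff(lengths) > 0):
            raise ValueError("lengths must be strictly increasing")
        if np.any(dt < 0):
            raise ValueError("relative_delta_T must be non-negative")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "relative_delta_T", dt)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"length_m": self.lengths, "relative_delta_T": self.relative_delta_T}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "HeatingCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["length_m"].to_numpy(), df["relative_delta_T"].to_numpy(), **meta)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "model": self.model,
                    "field": self.field_description,
                    "length_m": self.lengths.tolist(),
                    "relative_delta_T": self.relative_delta_T.tolist(),
                },
                indent=2,
            )
        )

    @property
    def peak_length(self) -> float:
        return float(self.lengths[int(np.argmax(self.relative_delta_T))])


# ---------------------------------------------------------------------------
# transfer functions


def sem_transfer(k: Wavenumber, l):
    """Simple exponential transfer function h(l) = exp(-i*k*l), l >= 0."""
    larr = np.asarray(l, dtype=float)
    if np.any(larr < 0):
        raise ValueError("arc length l must be >= 0")
    out = np.exp(-1j * k.as_complex * larr)
    return out if larr.ndim else complex(out)


def _tlm_denominator(k: Wavenumber, gamma: complex, d: float) -> complex:
    den = 1.0 - gamma * cmath.exp(-2j * k.as_complex * d)
    if abs(den) < _SINGULAR_TOL:
        raise SingularDenominatorError(
            f"transmission-line resonant pole: |1 - gamma*exp(-2ikd)| < {_SINGULAR_TOL} "
            f"at d = {d}, gamma = {gamma}"
        )
    return den


def tlm_transfer(k: Wavenumber, gamma: complex, l, d: float):
    """Transmission-line transfer function with l measured from the lead tip.

    h(0) = 1 and h reduces to the SEM form at gamma = 0.
    """
    larr = np.asarray(l, dtype=float)
    if np.any(larr < 0) or np.any(larr > d * (1 + 1e-12)):
        raise ValueError(f"arc length l must lie in [0, d={d}]")
    kc = k.as_complex
    den = _tlm_denominator(k, gamma, d)
    out = np.exp(-1j * kc * larr) * (1.0 - gamma * np.exp(-2j * kc * (d - larr))) / den
    return out if larr.ndim else complex(out)


def tlm_transfer_proximal(k: Wavenumber, gamma: complex, l_prime, d: float):
    """Transmission-line transfer function parameterized from the capped
    (device) end: l' = d - l.  Shares the tip-form normalization; for a
    symmetric incident field the two forms give the same |V|."""
    lp = np.asarray(l_prime, dtype=float)
    if np.any(lp < 0) or np.any(lp > d * (1 + 1e-12)):
        raise ValueError(f"arc length l' must lie in [0, d={d}]")
    kc = k.as_complex
    den = _tlm_denominator(k, gamma, d)
    out = np.exp(-1j * kc * (d - lp)) * (1.0 - gamma * np.exp(-2j * kc * lp)) / den
    return out if lp.ndim else complex(out)


# ---------------------------------------------------------------------------
# closed forms for a constant field


def closed_form_voltage_sem(E: complex, k: Wavenumber, d: float) -> complex:
    """Lead-tip voltage for the SEM under a constant tangential field E:

        V = E * (exp(-i*k*d) - 1) / (-i*k),

    with the analytic limit V = E*d as |k| -> 0 (unity transfer function).
    """
    if d < 0:
        raise ValueError("lead length d must be >= 0")
    kc = k.as_complex
    if abs(kc) == 0:
        return E * d
    return E * (cmath.exp(-1j * kc * d) - 1.0) / (-1j * kc)


def closed_form_voltage_tlm(E: complex, k: Wavenumber, gamma: complex, d: float) -> complex:
    """Lead-tip voltage for the TLM under a constant tangential field E:

        V = E * (1 - e^{-ikd}) * (1 - Gamma e^{-ikd}) / (i*k * (1 - Gamma e^{-2ikd})).

    Reduces to the SEM closed form at Gamma = 0; the |k| -> 0 limit is E*d
    (for Gamma != 1; Gamma = 1 with k = 0 is a resonant pole).
    """
    if d < 0:
        raise ValueError("lead length d must be >= 0")
    kc = k.as_complex
    if abs(kc) == 0:
        if abs(1.0 - gamma) < _SINGULAR_TOL:
            raise SingularDenominatorError("k = 0 with gamma = 1 is a resonant pole")
        return E * d
    den = _tlm_denominator(k, gamma, d)
    e1 = cmath.exp(-1j * kc * d)
    return E * (1.0 - e1) * (1.0 - gamma * e1) / (1j * kc * den)


def delta_T_sem(E_abs: float, k: Wavenumber, d) -> np.ndarray | float:
    """Relative temperature rise for the SEM, constant field of magnitude E_abs:

        delta_T = E^2/|k|^2 * (1 + e^{2 kI d} - 2 e^{kI d} cos(kR d)),

    equal to |closed_form_voltage_sem|^2.  Vectorized over d.
    """
    darr = np.asarray(d, dtype=float)
    if np.any(darr < 0):
        raise ValueError("lead length d must be >= 0")
    if k.magnitude == 0:
        out = (E_abs * darr) ** 2
        return out if darr.ndim else float(out)
    kR, kI = k.kR, k.kI
    out = (E_abs**2 / k.magnitude**2) * (
        1.0 + np.exp(2 * kI * darr) - 2.0 * np.exp(kI * darr) * np.cos(kR * darr)
    )
    return out if darr.ndim else float(out)


def delta_T_tlm(E_abs: float, k: Wavenumber, gamma, d) -> np.ndarray | float:
    """Relative temperature rise for the TLM, constant field of magnitude E_abs.

    For real gamma the explicit trigonometric/hyperbolic closed form is used:

        delta_T = E^2/|k|^2
                  * [ e^{-2kI d} + G^2 e^{2kI d} + 2G cos(2kR d) + (1+G)^2
                      - 2(1+G) cos(kR d) (e^{-kI d} + G e^{kI d}) ]
                  / [ e^{-2kI d} + G^2 e^{2kI d} - 2G cos(2kR d) ].

    A complex gamma falls back to |closed_form_voltage_tlm|^2, which the real
    form equals identically.
    """
    if isinstance(gamma, complex) and gamma.imag != 0:
        darr = np.asarray(d, dtype=float)
        v = np.vectorize(lambda x: abs(closed_form_voltage_tlm(E_abs, k, gamma, x)) ** 2)
        out = v(darr)
        return out if darr.ndim else float(out)
    G = float(np.real(gamma))
    darr = np.asarray(d, dtype=float)
    if np.any(darr < 0):
        raise ValueError("lead length d must be >= 0")
    if k.magnitude == 0:
        if abs(1.0 - G) < _SINGULAR_TOL:
            raise SingularDenominatorError("k = 0 with gamma = 1 is a resonant pole")
        out = (E_abs * darr) ** 2
        return out if darr.ndim else float(out)
    kR, kI = k.kR, k.kI
    em = np.exp(-2 * kI * darr)
    ep = np.exp(2 * kI * darr)
    den = em + G**2 * ep - 2 * G * np.cos(2 * kR * darr)
    if np.any(np.abs(den) < _SINGULAR_TOL):
        raise SingularDenominatorError("transmission-line resonant pole in delta_T denominator")
    num = (
        em
        + G**2 * ep
        + 2 * G * np.cos(2 * kR * darr)
        + (1 + G) ** 2
        - 2 * (1 + G) * np.cos(kR * darr) * (np.exp(-kI * darr) + G * np.exp(kI * darr))
    )
    out = (E_abs**2 / k.magnitude**2) * num / den
    return out if darr.ndim else float(out)


def heating_curve(
    model: TransferModel, lengths, E_abs: float = 1.0, field_description: str = "constant"
) -> HeatingCurve:
    """Closed-form relative delta_T over an array of lead lengths."""
    lengths = np.asarray(lengths, dtype=float)
    if model.kind is ModelKind.SEM:
        dt = delta_T_sem(E_abs, model.wavenumber, lengths)
    else:
        dt = delta_T_tlm(E_abs, model.wavenumber, model.gamma, lengths)
    return HeatingCurve(lengths, np.asarray(dt), model=model.describe(), field_description=field_description)


# ---------------------------------------------------------------------------
# numerical line integral


class EFieldSampler(Protocol):
    """Anything that can return the complex E-field vector at query points."""

    def sample(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        """(N, 3) real coordinates -> (N, 3) complex field values."""
        ...


def numerical_voltage(
    field: EFieldSampler,
    path: "WirePath",
    model: TransferModel,
    *,
    proximal_form: bool = False,
) -> complex:
    """Discrete-sum approximation of the lead-tip voltage line integral.

    Midpoint rule over the path segments: each segment contributes
    h(l_mid) * (E(midpoint) . dl), with l_mid the arc length of the segment
    midpoint measured from the lead tip (the first path point).  Converges to
    the closed forms under a constant field as the segment length shrinks.
    """
    if model.kind is ModelKind.TLM and model.lead_length is None:
        model = model.with_length(path.total_length)
    E_mid = field.sample(path.midpoints)  # raises for out-of-domain points
    h = model.transfer(path.midpoint_arclengths, proximal_form=proximal_form)
    contributions = h * np.einsum("ij,ij->i", E_mid, path.segments.astype(complex))
    return complex(np.sum(contributions))
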