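"""Complex wavenumbers of lossy media, insulators, and insulated conductors.

A medium is described by its relative permittivity, conductivity, and
relative permeability.  Waves propagating in a lossy medium carry a complex
wavenumber ``k = kR + i*kI``; throughout this package we adopt the loss
(engineering) sign convention

    kR >= 0,   kI <= 0,

so that a transfer function ``exp(-i*k*l)`` decays, never grows, with
distance ``l``.  The one exception is the argument of the Hankel functions
inside the insulated-antenna (King) wavenumber, which is evaluated in the
opposite convention (``Im >= 0``) because that is the convention of the
underlying antenna theory; the result is re-expressed in the package
convention before it is returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import hankel1

#: Vacuum permittivity, F/m.
EPS0: float = 8.8541878128e-12
#: Vacuum permeability, H/m.
MU0: float = 4e-7 * math.pi
#: Speed of light in vacuum, m/s (derived, keeps k = omega/c exact).
C0: float = 1.0 / math.sqrt(EPS0 * MU0)
#: Proton gyromagnetic ratio over 2*pi, Hz/T.
GAMMA_BAR_HZ_PER_T: float = 42.58e6


class SingularDenominatorError(ZeroDivisionError):
    """A resonant pole was hit (lossless wavenumber with full reflection)."""


@dataclass(frozen=True)
class MaterialProperties:
    """Electromagnetic description of a homogeneous medium.

    Parameters
    ----------
    relative_permittivity : float
        Relative permittivity (dimensionless, > 0).
    conductivity : float
        Conductivity in S/m (>= 0).
    relative_permeability : float
        Relative permeability (dimensionless, > 0).  Biological tissue and
        phantom gels are non-magnetic, so the default is 1.
    """

    relative_permittivity: float
    conductivity: float = 0.0
    relative_permeability: float = 1.0

    def __post_init__(self) -> None:
        if not self.relative_permittivity > 0:
            raise ValueError("relative_permittivity must be > 0")
        if self.conductivity < 0:
            raise ValueError("conductivity must be >= 0")
        if not self.relative_permeability > 0:
            raise ValueError("relative_permeability must be > 0")

    @property
    def permittivity(self) -> float:
        """Absolute permittivity epsilon, F/m."""
        return self.relative_permittivity * EPS0

    @property
    def permeability(self) -> float:
        """Absolute permeability mu, H/m."""
        return self.relative_permeability * MU0


@dataclass(frozen=True)
class Wavenumber:
    """Complex spatial frequency ``k = kR + i*kI`` in rad/m.

    Enforces the package sign convention ``kR >= 0`` and ``kI <= 0``.
    """

    kR: float
    kI: float = 0.0

    def __post_init__(self) -> None:
        if self.kR < 0:
            raise ValueError(f"kR must be >= 0, got {self.kR}")
        if self.kI > 0:
            raise ValueError(f"kI must be <= 0, got {self.kI}")

    @property
    def as_complex(self) -> complex:
        return complex(self.kR, self.kI)

    @property
    def magnitude(self) -> float:
        return math.hypot(self.kR, self.kI)

    @property
    def wavelength(self) -> float:
        """Wavelength lambda = 2*pi/kR, m."""
        if self.kR == 0:
            return math.inf
        return 2.0 * math.pi / self.kR

    @property
    def loss_ratio(self) -> float:
        """Dimensionless loss ratio ``u = -kI/kR``."""
        if self.kR == 0:
            return math.inf if self.kI < 0 else 0.0
        return -self.kI / self.kR + 0.0  # +0.0 avoids printing -0.0 for lossless media


@dataclass(frozen=True)
class WireGeometry:
    """Cross-section of an insulated wire: conductor radius ``a``, insulation
    outer radius ``b`` (both in meters), and the insulation's relative
    permittivity."""

    conductor_radius_a: float
    insulation_outer_radius_b: float
    insulation_relative_permittivity: float

    def __post_init__(self) -> None:
        if not 0 < self.conductor_radius_a < self.insulation_outer_radius_b:
            raise ValueError(
                "require 0 < conductor_radius_a < insulation_outer_radius_b, "
                f"got a={self.conductor_radius_a}, b={self.insulation_outer_radius_b}"
            )
        if self.insulation_relative_permittivity < 1:
            raise ValueError("insulation_relative_permittivity must be >= 1")

    @property
    def radius_ratio(self) -> float:
        return self.insulation_outer_radius_b / self.conductor_radius_a


def larmor_frequency(field_strength: float, gamma_bar: float = GAMMA_BAR_HZ_PER_T) -> float:
    """Proton Larmor frequency, Hz, at static field ``field_strength`` (T).

    ``gamma_bar`` is the gyromagnetic ratio over 2*pi in Hz/T and may be
    overridden; passing an explicit frequency to the wavenumber functions
    bypasses this constant entirely.
    """
    if field_strength <= 0:
        raise ValueError("field_strength must be > 0")
    return gamma_bar * field_strength


def medium_wavenumber(props: MaterialProperties, frequency: float) -> Wavenumber:
    """Complex wavenumber of a (possibly lossy) homogeneous medium.

    Uses the standard closed form for a conducting dielectric,

        kR =  omega * sqrt(eps*mu/2) * sqrt( sqrt(1 + (sigma/(eps*omega))^2) + 1 )
        kI = -omega * sqrt(eps*mu/2) * sqrt( sqrt(1 + (sigma/(eps*omega))^2) - 1 ),

    equivalent to the principal branch of ``omega*sqrt(mu*(eps + i*sigma/omega))``
    with the imaginary part flipped negative.  For ``sigma = 0`` the result is
    purely real, ``kR = omega*sqrt(eps*mu)``.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    omega = 2.0 * math.pi * frequency
    eps = props.permittivity
    mu = props.permeability
    loss_tangent = props.conductivity / (eps * omega)
    root = math.sqrt(1.0 + loss_tangent**2)
    scale = omega * math.sqrt(eps * mu / 2.0)
    kR = scale * math.sqrt(root + 1.0)
    # root - 1 rewritten as lt^2/(root + 1): identical algebra, no
    # cancellation for small loss tangents
    kI = -scale * abs(loss_tangent) / math.sqrt(root + 1.0)
    return Wavenumber(kR, kI)


def insulator_wavenumber(relative_permittivity: float, frequency: float) -> Wavenumber:
    """Real wavenumber ``omega*sqrt(eps*mu)`` of a lossless insulator."""
    if relative_permittivity < 1:
        raise ValueError("relative_permittivity must be >= 1")
    props = MaterialProperties(relative_permittivity, conductivity=0.0)
    k = medium_wavenumber(props, frequency)
    # sigma = 0 makes kI exactly 0 in the closed form; assert the invariant.
    return Wavenumber(k.kR, 0.0)


def king_wavenumber(
    insulator_k: Wavenumber, medium_k: Wavenumber, geometry: WireGeometry
) -> Wavenumber:
    """Wavenumber of current propagation along an insulated conductor embedded
    in a conductive medium, from insulated antenna theory.

        k = ki * [ 1 + F(kt*b) / ln(b/a) ]^(1/2),
        F(z) = H0(z) / (z * H1(z)),

    with ``H0``/``H1`` Hankel functions of the first kind, ``ki`` the
    insulator wavenumber, ``kt`` the embedding-medium wavenumber, and ``a``,
    ``b`` the conductor and insulation radii.  The antenna-theory derivation
    uses the opposite loss sign convention, so ``kt`` is conjugated
    (``Im >= 0``) inside the Hankel argument only; the principal square root
    with positive real part is taken and the result is returned with
    ``kI <= 0``.

    The theory assumes a conductive embedding medium; a lossless medium is
    accepted but a warning is emitted.
    """
    if medium_k.kI == 0:
        warnings.warn(
            "insulated-antenna wavenumber assumes a conductive embedding "
            "medium; a lossless medium (kI = 0) is outside its stated validity",
            UserWarning,
            stacklevel=2,
        )
    b = geometry.insulation_outer_radius_b
    a = geometry.conductor_radius_a
    z = np.conj(medium_k.as_complex) * b  # antenna-theory convention Im >= 0
    h1 = hankel1(1, z)
    if h1 == 0 or not np.isfinite(h1):
        raise ArithmeticError(f"Hankel function H1 vanishes or overflows at z = {z}")
    F = hankel1(0, z) / (z * h1)
    k = insulator_k.as_complex * np.sqrt(1.0 + F / math.log(b / a))
    if not np.isfinite(k):
        raise ArithmeticError(f"insulated-antenna wavenumber not finite for z = {z}")
    return Wavenumber(abs(k.real), -abs(k.imag))
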