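"""Isotropic linear-elastic material constants and bulk wave speeds.

Soft tissues and tissue-mimicking gels are nearly incompressible
(Poisson's ratio close to, but below, 0.5).  Everything downstream —
the time-domain engine, the stability analysis, the density-rescaling
trick — is driven by the two Lame constants and the two bulk wave
speeds derived here:

    mu     = E / (2 (1 + nu))                  (shear modulus G)
    lambda = E nu / ((1 + nu) (1 - 2 nu))
    V_L    = sqrt((lambda + 2 mu) / rho)       (longitudinal)
    V_T    = sqrt(mu / rho)                    (transverse / shear)

At nu = 0.495 the speed ratio V_L/V_T = sqrt(101) ~ 10, which is the
root of the numerical stiffness that motivates density rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import DomainError, IncompressibilityError

__all__ = ["ElasticMaterial", "WaveSpeeds", "lame_constants", "wave_speeds"]


@dataclass(frozen=True)
class ElasticMaterial:
    """Homogeneous isotropic elastic solid.

    Parameters
    ----------
    young_modulus : float
        Young's modulus E in Pa; must be positive.
    poisson_ratio : float
        Poisson's ratio nu, in [0, 0.5).  Exactly 0.5 (ideal
        incompressibility) is rejected: lambda diverges.
    density : float
        Mass density rho in kg/m^3; must be positive.
    """

    young_modulus: float
    poisson_ratio: float
    density: float

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise DomainError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not self.density > 0:
            raise DomainError(f"density must be > 0, got {self.density}")
        if self.poisson_ratio == 0.5:
            raise IncompressibilityError(
                "poisson_ratio = 0.5 is not representable (lambda diverges); "
                "use a value below 0.5, e.g. 0.495"
            )
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise DomainError(
                f"poisson_ratio must lie in [0, 0.5), got {self.poisson_ratio}"
            )

    @property
    def lame_mu(self) -> float:
        """Shear modulus mu = G = E / (2 (1 + nu)) in Pa."""
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def lame_lambda(self) -> float:
        """First Lame constant lambda = E nu / ((1 + nu)(1 - 2 nu)) in Pa."""
        nu = self.poisson_ratio
        return self.young_modulus * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))

    @property
    def p_wave_modulus(self) -> float:
        """lambda + 2 mu, the modulus governing longitudinal waves."""
        return self.lame_lambda + 2.0 * self.lame_mu

    def with_density(self, density: float) -> "ElasticMaterial":
        """Copy of this material with a different density (E, nu unchanged)."""
        return replace(self, density=density)


@dataclass(frozen=True)
class WaveSpeeds:
    """Bulk wave speeds of an unbounded medium, m/s."""

    longitudinal: float
    transverse: float

    def __post_init__(self) -> None:
        if not self.transverse > 0 or not self.longitudinal > self.transverse:
            raise DomainError(
                "wave speeds must satisfy longitudinal > transverse > 0, got "
                f"({self.longitudinal}, {self.transverse})"
            )

    @property
    def ratio(self) -> float:
        """V_L / V_T = sqrt((2 - 2 nu) / (1 - 2 nu))."""
        return self.longitudinal / self.transverse


def lame_constants(material: ElasticMaterial) -> tuple[float, float]:
    """Return ``(lame_lambda, lame_mu)`` in Pa for *material*."""
    return material.lame_lambda, material.lame_mu


def wave_speeds(material: ElasticMaterial) -> WaveSpeeds:
    """Bulk longitudinal and transverse speeds of *material*.

    V_L = sqrt((lambda + 2 mu) / rho), V_T = sqrt(mu / rho).  Scaling the
    density by S divides both speeds by sqrt(S) exactly — the identity
    the rescaling module is built on.
    """
    rho = material.density
    return WaveSpeeds(
        longitudinal=math.sqrt(material.p_wave_modulus / rho),
        transverse=math.sqrt(material.lame_mu / rho),
    )
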