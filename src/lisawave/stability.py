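"""Courant numbers, von Neumann analysis and the 1D reference scheme.

The explicit leapfrog update of the scalar wave equation,

    u_i^{n+1} = -u_i^{n-1} + 2 u_i^n + C^2 (u_{i+1}^n - 2 u_i^n + u_{i-1}^n),

with Courant number C = c dt / dx, is the analytically tractable model
for the full elastodynamic engine.  Its amplification polynomial is

    g^2 - 2 (1 - 2 C^2 s^2) g + 1 = 0,        s = sin(k dx / 2),

whose roots lie on the unit circle iff C s <= 1.  The package also
carries the quartic expression

    g = 8 C^4 s^4 - 8 C^2 s^2 + 1

used in the source analysis of the scheme.  Note that for the stable,
non-dissipative leapfrog scheme this quantity is not a root magnitude:
it equals cos(2 theta), twice the phase angle of the (unit-magnitude)
complex root pair.  ``von_neumann_roots`` is the rigorous stability
check; ``amplification_factor`` reproduces the quartic verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ShapeError
from .materials import ElasticMaterial, wave_speeds

__all__ = [
    "courant_number",
    "limit_velocity",
    "amplification_factor",
    "von_neumann_roots",
    "step_1d",
    "StabilityReport",
    "stability_report",
    "courant_bound",
    "scheme_stability_limit_dt",
]


def courant_number(speed: float, dt: float, dx: float) -> float:
    """Dimensionless Courant (CFL) number C = speed * dt / dx."""
    if speed <= 0 or dt <= 0 or dx <= 0:
        raise DomainError("speed, dt and dx must all be positive")
    return speed * dt / dx


def limit_velocity(dx: float, dt: float) -> float:
    """Grid limit velocity V_lim = dx / dt, the fastest representable speed."""
    if dx <= 0 or dt <= 0:
        raise DomainError("dx and dt must be positive")
    return dx / dt


def amplification_factor(courant: float, s):
    """Quartic amplification expression g = 8 C^4 s^4 - 8 C^2 s^2 + 1.

    Parameters
    ----------
    courant : float
        Courant number C >= 0.
    s : float or array
        Normalised wavenumber s = sin(k dx / 2), in [0, 1].

    For a stable scheme (C <= 1) this equals cos(2 theta) of the root
    phase theta and stays within [-1, 1]; for C > 1 it exceeds 1 at
    s = 1.  g = 1 at s = 0 for any C.
    """
    if courant < 0:
        raise DomainError("courant must be >= 0")
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise DomainError("s must lie in [0, 1]")
    x = (courant * s) ** 2
    out = 8.0 * x * x - 8.0 * x + 1.0
    return float(out) if out.ndim == 0 else out


def von_neumann_roots(courant: float, k_dx: float) -> tuple[complex, complex]:
    """Both roots of the leapfrog amplification polynomial.

    The polynomial g^2 - 2 (1 - 2 C^2 s^2) g + 1 = 0 with
    s = sin(k_dx / 2) has unit-magnitude conjugate roots iff
    C |s| <= 1; otherwise one real root has magnitude > 1 and the mode
    grows (instability).
    """
    if courant < 0:
        raise DomainError("courant must be >= 0")
    s = math.sin(k_dx / 2.0)
    b = 1.0 - 2.0 * (courant * s) ** 2  # half the linear coefficient
    disc = b * b - 1.0
    if disc <= 0:
        root = complex(b, math.sqrt(-disc))
        return root, root.conjugate()
    sq = math.sqrt(disc)
    return complex(b + sq), complex(b - sq)


def step_1d(
    u_prev: np.ndarray,
    u_curr: np.ndarray,
    courant: float,
    boundary: str = "fixed",
) -> np.ndarray:
    """One leapfrog step of the 1D scheme; returns u at the next level.

    Interior nodes follow the stencil above; endpoints follow
    *boundary*: ``"fixed"`` clamps them to zero, ``"free"`` applies a
    one-sided mirror (zero-gradient ghost node).
    """
    u_prev = np.asarray(u_prev, dtype=float)
    u_curr = np.asarray(u_curr, dtype=float)
    if u_prev.shape != u_curr.shape or u_curr.ndim != 1 or u_curr.size < 3:
        raise ShapeError(
            f"u_prev and u_curr must be equal-length 1D arrays of >= 3 samples, "
            f"got {u_prev.shape} and {u_curr.shape}"
        )
    if boundary not in ("fixed", "free"):
        raise DomainError(f"unknown boundary kind {boundary!r}")
    c2 = courant * courant
    u_next = np.empty_like(u_curr)
    u_next[1:-1] = (
        -u_prev[1:-1]
        + 2.0 * u_curr[1:-1]
        + c2 * (u_curr[2:] - 2.0 * u_curr[1:-1] + u_curr[:-2])
    )
    if boundary == "fixed":
        u_next[0] = 0.0
        u_next[-1] = 0.0
    else:  # mirror ghost: u[-1] := u[1], u[n] := u[n-2]
        u_next[0] = -u_prev[0] + 2.0 * u_curr[0] + c2 * 2.0 * (u_curr[1] - u_curr[0])
        u_next[-1] = -u_prev[-1] + 2.0 * u_curr[-1] + c2 * 2.0 * (
            u_curr[-2] - u_curr[-1]
        )
    return u_next


def courant_bound(ndim: int) -> float:
    """Scalar-scheme Courant bound 1/sqrt(ndim) used for the report flag."""
    if ndim not in (1, 2, 3):
        raise DomainError("ndim must be 1, 2 or 3")
    return 1.0 / math.sqrt(ndim)


def scheme_stability_limit_dt(material: ElasticMaterial, spacings) -> float:
    """Largest stable time step of the collocated elastodynamic stencil.

    Von Neumann analysis of the central-difference discretisation of
    mu lap(W) + (lambda + mu) grad(div W) = rho Wtt gives the symbol

        Lambda(theta) = sum_i [4 mu sin^2(theta_i/2)
                               + (lambda + mu) sin^2(theta_i)] / dx_i^2 / rho

    (the mixed-derivative four-point stencil contributes sin(theta_i)
    factors that vanish at the Nyquist wavenumber, which is why this
    bound is laxer than the scalar-scheme 1/sqrt(ndim)).  Per axis the
    bracket is maximised at cos(theta) = -mu/(lambda + mu), giving

        h_max = lambda + 3 mu + mu^2 / (lambda + mu),

    and leapfrog requires dt <= 2 / sqrt(Lambda_max).
    """
    lam, mu = material.lame_lambda, material.lame_mu
    h_max = lam + 3.0 * mu + mu * mu / (lam + mu)
    lam_max = sum(h_max / (dx * dx) for dx in spacings) / material.density
    return 2.0 / math.sqrt(lam_max)


@dataclass(frozen=True)
class StabilityReport:
    """Stability summary of a (material, dx, dt) combination."""

    courant_longitudinal: float
    courant_transverse: float
    limit_velocity: float
    stable: bool
    #: mapping s in [0, 1] -> quartic amplification expression at C_T
    amplification_profile: dict[float, float]


def stability_report(
    material: ElasticMaterial,
    dx: float,
    dt: float,
    ndim: int = 3,
    n_profile: int = 21,
) -> StabilityReport:
    """Courant numbers and stability flag for a uniform grid.

    The ``stable`` flag compares the longitudinal Courant number with
    the conservative scalar-scheme bound 1/sqrt(ndim); the time-domain
    engine itself admits a somewhat larger step (see
    :func:`scheme_stability_limit_dt`).
    """
    v = wave_speeds(material)
    vlim = limit_velocity(dx, dt)
    c_l = courant_number(v.longitudinal, dt, dx)
    c_t = courant_number(v.transverse, dt, dx)
    s_grid = np.linspace(0.0, 1.0, n_profile)
    profile = {float(s): float(amplification_factor(c_t, s)) for s in s_grid}
    return StabilityReport(
        courant_longitudinal=c_l,
        courant_transverse=c_t,
        limit_velocity=vlim,
        stable=c_l <= courant_bound(ndim),
        amplification_profile=profile,
    )
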