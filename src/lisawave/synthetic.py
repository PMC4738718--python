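"""Synthetic waveform generation for estimator validation.

Profiles emulate what a radial measurement ray through a driven
phantom looks like: a decaying sinusoid A exp(-x/L) sin(2 pi x / wl)
with optional additive Gaussian noise.  Ground truth is known exactly,
which makes these the test surface for the wavelength estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientExtentError
from .measurement import LineWaveform

__all__ = ["SyntheticWaveSpec", "make_synthetic_profile"]


@dataclass(frozen=True)
class SyntheticWaveSpec:
    """Parameters of a synthetic decaying-sinusoid profile.

    ``decay_length`` may be ``inf`` for a pure sinusoid; ``noise_sd``
    is the standard deviation of additive Gaussian noise (m); ``seed``
    makes the noise reproducible.  The extent must cover at least four
    wavelengths so that peak statistics are meaningful.
    """

    wavelength: float  # m
    extent: float  # m
    sampling: float  # m
    amplitude: float = 1e-6
    decay_length: float = float("inf")
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.wavelength <= 0 or self.sampling <= 0 or self.amplitude <= 0:
            raise DomainError("wavelength, sampling and amplitude must be positive")
        if self.decay_length <= 0:
            raise DomainError("decay_length must be positive (may be inf)")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.extent < 4.0 * self.wavelength:
            raise InsufficientExtentError(
                f"extent {self.extent} m must cover at least four wavelengths "
                f"({4 * self.wavelength} m)"
            )


def make_synthetic_profile(spec: SyntheticWaveSpec) -> LineWaveform:
    """Generate A exp(-x/L) sin(2 pi x / wl) + noise on a uniform grid.

    Deterministic for a given ``spec.seed`` (one explicit generator, no
    global random state).
    """
    n = int(np.floor(spec.extent / spec.sampling)) + 1
    x = np.arange(n) * spec.sampling
    envelope = spec.amplitude * np.exp(-x / spec.decay_length)
    y = envelope * np.sin(2.0 * np.pi * x / spec.wavelength)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    return LineWaveform(positions=x, displacements=y)
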