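"""Wavelength estimation and shear-modulus inversion.

Mirrors the standard MR-elastography post-processing chain: sample a
displacement profile along a ray from the driver, estimate the shear
wavelength lambda from the spacing of successive wave peaks (or from
the dominant spatial wavenumber), and invert

    G = rho (lambda f)^2

for the shear modulus, which follows from lambda = V_T / f and
V_T = sqrt(G / rho).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import (
    DomainError,
    InsufficientPeaksError,
    NoDominantWavenumberError,
    OrderingError,
    ProfileBoundsError,
    ShapeError,
)

__all__ = [
    "LineWaveform",
    "WavelengthEstimate",
    "estimate_wavelength_peaks",
    "estimate_wavelength_spectral",
    "shear_modulus_from_wavelength",
    "extract_line_profile",
    "find_profile_peaks",
]

_SPACING_TOL = 1e-9  # m; uniformity tolerance of the position grid


@dataclass(frozen=True)
class LineWaveform:
    """Uniformly sampled (position, displacement) profile at one instant."""

    positions: np.ndarray  # m, strictly increasing, uniform spacing
    displacements: np.ndarray  # m
    time_stamp: float = 0.0
    component: str = "y"

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(
            self, "displacements", np.asarray(self.displacements, float)
        )
        if self.positions.ndim != 1 or self.positions.shape != self.displacements.shape:
            raise ShapeError("positions and displacements must be equal-length 1D")
        if self.positions.size < 8:
            raise ShapeError("a line waveform needs at least 8 samples")
        steps = np.diff(self.positions)
        if np.any(steps <= 0):
            raise OrderingError("positions must be strictly increasing")
        if steps.max() - steps.min() > _SPACING_TOL:
            raise OrderingError("positions must be uniformly spaced")

    @property
    def spacing(self) -> float:
        return float(np.mean(np.diff(self.positions)))

    @property
    def extent(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass(frozen=True)
class WavelengthEstimate:
    """Mean/std of a wavelength measurement, m."""

    mean: float
    std: float
    n_intervals: int
    method: str

    def __post_init__(self):
        if not self.mean > 0 or self.std < 0 or self.n_intervals < 1:
            raise DomainError("invalid wavelength estimate")


def _smooth(y: np.ndarray) -> np.ndarray:
    # 3-point moving average; endpoint handling by edge replication
    return uniform_filter1d(y, size=3, mode="nearest")


def find_profile_peaks(
    profile: LineWaveform,
    smooth: bool = True,
    min_prominence_fraction: float = 0.05,
) -> np.ndarray:
    """Indices of strict local maxima of the (smoothed) profile.

    A sample is a peak when it exceeds its left neighbour and is at
    least as large as its right neighbour, which breaks plateau ties
    toward the smaller position.  Candidates whose prominence falls
    below ``min_prominence_fraction`` of the profile's full range are
    discarded as noise ripple.
    """
    from scipy.signal import peak_prominences

    y = _smooth(profile.displacements) if smooth else profile.displacements
    inner = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    idx = np.flatnonzero(inner) + 1
    if idx.size == 0 or min_prominence_fraction <= 0:
        return idx
    prom = peak_prominences(y, idx)[0]
    threshold = min_prominence_fraction * (y.max() - y.min())
    kept = idx[prom >= threshold]
    return kept if kept.size else idx[[np.argmax(prom)]]


def peak_intervals(
    profile: LineWaveform,
    smooth: bool = True,
    exclude_near_field: bool = False,
) -> np.ndarray:
    """Successive peak-to-peak distances of a profile.

    With ``exclude_near_field`` the first peak is dropped when it lies
    within one (estimated) wavelength of the start of the ray — the
    region distorted by the source.
    """
    peaks = find_profile_peaks(profile, smooth=smooth)
    if peaks.size < 2:
        raise InsufficientPeaksError(int(peaks.size))
    pos = profile.positions[peaks]
    intervals = np.diff(pos)
    if exclude_near_field and peaks.size >= 3:
        if pos[0] - profile.positions[0] < np.median(intervals):
            intervals = intervals[1:]
    return intervals


def estimate_wavelength_peaks(
    profile: LineWaveform,
    smooth: bool = True,
    exclude_near_field: bool = False,
) -> WavelengthEstimate:
    """Wavelength from the mean spacing of adjacent wave peaks.

    The profile is smoothed with a 3-point moving average before peak
    picking; mean and (population) std are taken over the successive
    peak-to-peak intervals.  Raises
    :class:`~lisawave.errors.InsufficientPeaksError` when fewer than
    two peaks are found.
    """
    intervals = peak_intervals(
        profile, smooth=smooth, exclude_near_field=exclude_near_field
    )
    return WavelengthEstimate(
        mean=float(np.mean(intervals)),
        std=float(np.std(intervals)),
        n_intervals=int(intervals.size),
        method="peaks",
    )


def estimate_wavelength_spectral(
    profile: LineWaveform, pad_factor: int = 8, min_contrast: float = 3.0
) -> WavelengthEstimate:
    """Wavelength from the dominant peak of the windowed spatial spectrum.

    The profile is mean-removed, Hann-windowed and zero-padded; the
    spectral peak location is refined by parabolic interpolation and
    the spread is taken from the peak's half-power width.  Raises
    :class:`~lisawave.errors.NoDominantWavenumberError` when the
    spectrum has no clear peak (contrast below ``min_contrast`` over
    the median level).
    """
    y = profile.displacements
    if y.size < 16:
        raise ShapeError("spectral estimation needs at least 16 samples")
    dx = profile.spacing
    yw = (y - y.mean()) * np.hanning(y.size)
    n = int(2 ** np.ceil(np.log2(y.size * pad_factor)))
    spec = np.abs(np.fft.rfft(yw, n=n))
    freqs = np.fft.rfftfreq(n, d=dx)  # cycles per metre
    # ignore the DC lobe: skip bins below one cycle per full extent
    k0 = max(1, int(np.ceil(n * dx / max(profile.extent, dx))))
    band = spec[k0:]
    if band.max() < min_contrast * max(np.median(band), 1e-300):
        raise NoDominantWavenumberError("no dominant spatial wavenumber found")
    i = int(np.argmax(band)) + k0
    # parabolic refinement on the amplitude spectrum
    if 0 < i < spec.size - 1:
        a, b, c = spec[i - 1], spec[i], spec[i + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    else:
        delta = 0.0
    f_peak = (i + delta) / (n * dx)
    wavelength = 1.0 / f_peak
    # half-power width -> wavelength spread
    half = spec[i] / np.sqrt(2.0)
    lo = i
    while lo > 0 and spec[lo] > half:
        lo -= 1
    hi = i
    while hi < spec.size - 1 and spec[hi] > half:
        hi += 1
    df = (hi - lo) / (2.0 * n * dx)
    std = wavelength * df / max(f_peak, 1e-300)
    return WavelengthEstimate(
        mean=float(wavelength), std=float(std), n_intervals=1, method="spectral"
    )


def shear_modulus_from_wavelength(
    wavelength: float, frequency: float, density: float
) -> float:
    """Shear modulus G = rho (wavelength * frequency)^2 in Pa."""
    if wavelength <= 0 or frequency <= 0 or density <= 0:
        raise DomainError("wavelength, frequency and density must be positive")
    return density * (wavelength * frequency) ** 2


def extract_line_profile(
    snapshot: np.ndarray,
    grid,
    start,
    axis: int = 0,
    component: int | str = "y",
    n_samples: int | None = None,
    direction: int = +1,
    time_stamp: float = 0.0,
) -> LineWaveform:
    """Sample one displacement component along a grid-aligned ray.

    ``snapshot`` is an engine field of shape (ndim, *node_shape);
    the ray starts at node index ``start`` and walks along ``axis`` in
    ``direction`` for ``n_samples`` nodes (to the boundary when None).
    Positions are measured from the start node.  Raises
    :class:`~lisawave.errors.ProfileBoundsError` when the ray leaves
    the grid.
    """
    from .grid import _axis_index  # local import to avoid cycle at import time

    comp = _axis_index(component, grid.ndim)
    field = snapshot[comp]
    start = tuple(int(i) for i in start)
    if len(start) != grid.ndim:
        raise ShapeError("start index dimensionality mismatch")
    limit = field.shape[axis]
    if direction not in (+1, -1):
        raise DomainError("direction must be +1 or -1")
    available = (limit - start[axis]) if direction > 0 else (start[axis] + 1)
    if n_samples is None:
        n_samples = available
    if n_samples > available or n_samples < 1:
        raise ProfileBoundsError(
            f"ray of {n_samples} samples leaves the grid (room for {available})"
        )
    idx = start[axis] + direction * np.arange(n_samples)
    sel = list(start)
    sel[axis] = idx
    values = field[tuple(sel)]
    positions = np.arange(n_samples) * grid.spacings[axis]
    return LineWaveform(
        positions=positions,
        displacements=np.asarray(values, float),
        time_stamp=time_stamp,
        component="xyz"[comp],
    )
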