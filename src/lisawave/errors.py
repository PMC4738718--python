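"""Exception types shared across the package."""


class LisaWaveError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LisaWaveError, ValueError):
    """An argument is outside its physically admissible range."""


class IncompressibilityError(DomainError):
    """Poisson's ratio of exactly 0.5 makes the first Lame constant infinite."""


class DegenerateGeometryError(LisaWaveError, ValueError):
    """Requested geometry cannot be resolved on the requested grid."""


class MeshError(LisaWaveError, ValueError):
    """Inconsistent voxel mesh (e.g. a node with no adjacent material cell)."""


class ShapeError(LisaWaveError, ValueError):
    """Array arguments have incompatible shapes."""


class InstabilityError(LisaWaveError, RuntimeError):
    """The time stepper produced non-finite fields."""

    def __init__(self, step_index: int, message: str | None = None):
        self.step_index = step_index
        super().__init__(
            message or f"non-finite displacement detected at step {step_index}"
        )


class InsufficientPeaksError(LisaWaveError, ValueError):
    """Fewer than two local maxima were found in a waveform profile."""

    def __init__(self, n_found: int):
        self.n_found = n_found
        super().__init__(
            f"wavelength estimation needs at least 2 peaks, found {n_found}"
        )


class NoDominantWavenumberError(LisaWaveError, ValueError):
    """The spatial spectrum of a profile has no dominant component."""


class InsufficientExtentError(LisaWaveError, ValueError):
    """A synthetic profile extent is too short for its wavelength."""


class NoPropagatingModeError(LisaWaveError, ValueError):
    """The guided-wave solver found no real propagating mode."""


class ProfileBoundsError(LisaWaveError, IndexError):
    """A requested sampling ray leaves the simulation grid."""


class OrderingError(LisaWaveError, ValueError):
    """Positions of a line waveform are not strictly increasing."""


class ConfigError(LisaWaveError, ValueError):
    """Malformed or unknown configuration content."""
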