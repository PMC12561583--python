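"""Exception types shared across the package."""


class CrpCoordError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CrpCoordError):
    """A table is missing required columns or has a malformed header."""


class ValidationError(CrpCoordError):
    """Data are structurally present but violate an invariant."""


class ConfigError(CrpCoordError):
    """An analysis configuration value is out of range or inconsistent."""


class DegenerateSignalError(CrpCoordError):
    """A signal has no usable amplitude (constant angle or zero velocity)."""


class UndefinedPhaseError(CrpCoordError):
    """A phase-plane point sits at the origin, where the angle is undefined."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(
            f"phase angle undefined at sample indices {self.indices}: "
            "phase-plane point is at the origin"
        )


class InsufficientReplicatesError(CrpCoordError):
    """An operation needs more repeated curves/trials than were provided."""
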