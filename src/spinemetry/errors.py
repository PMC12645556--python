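"""Exception hierarchy shared by all spinemetry modules."""


class SpinemetryError(Exception):
    """Base class for all package errors."""


class FormatError(SpinemetryError):
    """A file does not conform to the expected on-disk schema."""


class ValidationError(SpinemetryError):
    """Input data violates a documented invariant."""


class UsageError(SpinemetryError):
    """An operation was called with inconsistent or unsupported options."""


class GeometryError(SpinemetryError):
    """Degenerate geometry (duplicate points, vanishing tangent, bad projection)."""
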