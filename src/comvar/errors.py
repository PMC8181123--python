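"""Exception hierarchy shared across the package."""


class ComvarError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(ComvarError):
    """A geometric solid was given non-positive or inconsistent dimensions."""


class ConfigurationError(ComvarError):
    """A profile or run configuration is incomplete or inconsistent."""


class SchemaError(ComvarError):
    """An input file does not match its documented schema."""


class DetectionError(ComvarError):
    """Gait-event detection failed to find a plausible event pattern."""


class UndefinedCVError(ComvarError):
    """Coefficient of variation requested for data with non-positive mean."""


class DegenerateTestError(ComvarError):
    """A t-test was requested on data with zero variance."""
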