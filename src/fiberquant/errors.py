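"""Exception hierarchy shared across the package."""


class FiberquantError(Exception):
    """Base class for all package errors."""


class ConfigError(FiberquantError, ValueError):
    """Invalid configuration or parameter value."""


class FormatError(FiberquantError, ValueError):
    """A file does not conform to the expected dialect."""


class IntegrityError(FiberquantError, ValueError):
    """Parsed data violates a structural invariant."""


class AlignmentError(FiberquantError, ValueError):
    """Behaviour and photometry time ranges cannot be aligned."""


class ThresholdError(FiberquantError, ValueError):
    """Automatic intensity thresholding is not defined for the input."""
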