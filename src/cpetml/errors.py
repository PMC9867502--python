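"""Exception hierarchy shared across the package."""


class CPETError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CPETError):
    """A file does not conform to the canonical CPET CSV / label JSON dialect."""


class ValidationError(CPETError):
    """Data violates a structural invariant (e.g. non-increasing time)."""


class InsufficientDataError(CPETError):
    """Too few samples for the requested operation."""


class DegenerateValueError(CPETError):
    """A physically impossible value (e.g. VO2 <= 0) blocks a derivation."""


class TooShortTestError(CPETError):
    """The test is shorter than one rolling window."""


class ConfigError(CPETError):
    """An invalid simulator / experiment configuration."""
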