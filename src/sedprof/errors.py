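"""Exception types shared across the package."""


class SedprofError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SedprofError, ValueError):
    """A file does not conform to the documented TSV dialect."""


class ValidationError(SedprofError, ValueError):
    """A record or parameter violates a documented invariant."""


class ConfigError(SedprofError, ValueError):
    """A configuration is internally inconsistent or incomplete."""
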