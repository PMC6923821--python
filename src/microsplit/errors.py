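"""Exception hierarchy shared across the package."""


class MicrosplitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MicrosplitError, ValueError):
    """A file or string could not be parsed into a domain object."""


class ValidationError(MicrosplitError, ValueError):
    """An object violates a domain invariant (negative abundance, NaN, ...)."""


class AlignmentError(MicrosplitError, ValueError):
    """Two inputs that must share sample labels do not."""


class ConfigError(MicrosplitError, ValueError):
    """A simulation or run configuration is internally inconsistent."""
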