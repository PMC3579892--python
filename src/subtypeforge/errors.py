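"""Exception types shared across the package."""


class SubtypeForgeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SubtypeForgeError):
    """Invalid simulation or pipeline configuration."""


class ParseError(SubtypeForgeError):
    """Malformed on-disk input (names the offending row/column where possible)."""


class DataError(SubtypeForgeError):
    """Input data violate a precondition of an operation."""
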