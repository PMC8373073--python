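"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: ValidationError/ConfigError -> 2, IOError
subtypes -> 3. Library code raises these directly; it never calls sys.exit.
"""


class DenoiseqError(Exception):
    """Base class for all package errors."""


class ValidationError(DenoiseqError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(DenoiseqError, ValueError):
    """A file does not conform to its declared format."""


class ConfigError(DenoiseqError, ValueError):
    """An unknown format, measure, method, or inconsistent option set."""


class InputOutputError(DenoiseqError, OSError):
    """A file is missing, unreadable, or unwritable."""
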