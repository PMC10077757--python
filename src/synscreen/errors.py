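"""Exception hierarchy shared across the package.

All user-facing errors derive from :class:`SynscreenError` so callers (and
the CLI) can distinguish bad input (exit code 1) from internal faults
(exit code 2).
"""


class SynscreenError(Exception):
    """Base class for all errors raised on invalid user input or data."""


class SchemaError(SynscreenError):
    """A table is missing required columns or has an unknown layout."""


class ValidationError(SynscreenError):
    """A value violates a data invariant (negative signal, bad role, ...)."""


class DegeneratePlateError(SynscreenError):
    """Plate controls cannot define the 0-100% viability scale."""


class InsufficientDataError(SynscreenError):
    """Too few observations for the requested fit or test."""


class ConfigError(SynscreenError):
    """A run configuration is unparseable, unknown or out of range."""
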