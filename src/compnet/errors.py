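"""Exception hierarchy shared across the package.

All domain errors derive from :class:`CompnetError` so callers (and the CLI)
can distinguish user/data problems (exit code 2) from genuine bugs.
"""


class CompnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CompnetError):
    """A file or serialized artifact is structurally malformed."""


class ValidationError(CompnetError):
    """Inputs are well-formed but violate a domain invariant."""


class ImpossibleEvidenceError(CompnetError):
    """A conditional query was posed on evidence with probability zero."""
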