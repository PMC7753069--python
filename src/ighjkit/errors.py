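"""Exception hierarchy shared across ighjkit modules."""


class IghjkitError(Exception):
    """Base class for all package errors."""


class ConfigError(IghjkitError):
    """Malformed germline or efficiency configuration; names the offending gene/field."""


class ConsistencyError(IghjkitError):
    """A mutation's from-base does not match the consensus at that position."""

    def __init__(self, message: str, expected: str | None = None, found: str | None = None):
        super().__init__(message)
        self.expected = expected
        self.found = found


class StructuralError(IghjkitError):
    """Sequence lengths or shapes incompatible with the requested operation."""


class CompositionUnavailable(IghjkitError):
    """Spacer is represented by declared length only; base composition unknown."""


class NoRSSFound(IghjkitError):
    """No RSS decomposition within the mismatch budget."""


class DegenerateModelError(IghjkitError):
    """All gene weights are zero; the efficiency model cannot be normalised."""


class FormatError(IghjkitError):
    """Input table missing mandatory columns or otherwise unreadable."""


class ParameterError(IghjkitError):
    """Invalid simulation or analysis parameter."""


class EmptyStratumError(IghjkitError):
    """A usage profile was requested for a stratum with no records."""


class DegenerateAnovaError(IghjkitError):
    """Zero within-group variance in every group; the F statistic is undefined."""
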