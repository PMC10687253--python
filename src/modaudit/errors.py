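"""Exception hierarchy for the audit pipeline.

Every error raised on user input derives from :class:`ModAuditError` so that
callers (and the CLI) can distinguish "bad input" from genuine bugs.
"""


class ModAuditError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ModAuditError):
    """A file does not conform to its declared dialect.

    Carries ``line`` (1-based line number in the offending file) when known.
    """

    def __init__(self, message: str, line: int | None = None, path: str | None = None):
        self.line = line
        self.path = path
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class DuplicateIdError(FormatError):
    """Two records in one reference set share an id."""


class ConsistencyError(ModAuditError):
    """A record violates an internal invariant (e.g. mod_count > depth)."""


class JoinError(ModAuditError):
    """Two per-site tracks cannot be joined position-for-position."""


class UnknownTranscriptError(ModAuditError):
    """A site references a transcript id absent from the reference set."""


class InsufficientDataError(ModAuditError):
    """Too few records to run the requested analysis."""


class InputError(ModAuditError):
    """Arguments that violate an operation's preconditions."""


class ComparisonError(ModAuditError):
    """A group comparison cannot be formed (e.g. an empty group)."""


class DegenerateVarianceError(ComparisonError):
    """Pooled standard deviation is zero; effect sizes are undefined."""


class ConfigError(ModAuditError):
    """A simulation or run configuration is invalid."""
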