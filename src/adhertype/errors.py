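"""Exception types shared across the pipeline."""


class AdherTypeError(Exception):
    """Base class for package errors."""


class ConfigurationError(AdherTypeError, ValueError):
    """Invalid generator or pipeline configuration."""


class EventParseError(AdherTypeError, ValueError):
    """An event-log record could not be parsed.

    Carries the 1-based line numbers of the offending records so that
    dirty input files can be triaged without re-running the parser.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class UndefinedProfileError(AdherTypeError, ValueError):
    """Adherence measures are undefined (zero observed days)."""
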