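"""Exception hierarchy for the htsumd package."""


class HtSumdError(Exception):
    """Base class for all package errors."""


class ParseError(HtSumdError):
    """Malformed input file; carries the offending line or molecule."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyStructureError(HtSumdError):
    """A structure file yielded zero atoms."""


class LookupResidueError(HtSumdError):
    """A requested residue id is not present in the receptor."""


class PlacementError(HtSumdError):
    """No collision-free placement direction could be found."""


class ClashError(HtSumdError):
    """Receptor-fragment atom pair closer than the hard steric limit."""


class BackendError(HtSumdError):
    """The dynamics backend produced non-finite coordinates."""


class UnidentifiableError(HtSumdError):
    """A titration carries no usable binding signal."""


class ValidationError(HtSumdError):
    """Inconsistent inputs to an analysis operation."""


class ConfigError(HtSumdError):
    """Invalid run configuration or unknown policy."""
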