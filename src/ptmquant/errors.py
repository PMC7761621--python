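"""Exception hierarchy.

``ConfigurationError`` signals a problem with how a run was set up (missing
columns, unknown modification names, bad parameters); ``DataError`` signals a
problem with the data itself.  The CLI maps these to exit codes 2 and 3.
"""


class PTMQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PTMQuantError):
    """Invalid run configuration: missing column, unknown token, bad option."""


class EvidenceParseError(PTMQuantError):
    """A row or token in an evidence table could not be parsed."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DataError(PTMQuantError):
    """The inputs are structurally valid but the requested quantity is undefined."""


class NoPairError(DataError):
    """No modified/reference peptide-form pair covers the requested site."""


class AmbiguousPairError(DataError):
    """More than one candidate form per role and no tie-break was allowed."""


class UndefinedRatioError(DataError):
    """Occupancy ratio with a zero or negative reference intensity."""


class UndefinedShareError(DataError):
    """Relative abundance shares with zero total intensity."""
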