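"""Exception hierarchy for the pipeline."""


class PsgscanError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(PsgscanError, ValueError):
    pass


class InvalidTreeError(PsgscanError):
    pass


class UnknownBranchError(PsgscanError, KeyError):
    pass


class MissingForegroundError(PsgscanError):
    pass


class SpeciesMismatchError(PsgscanError):
    pass


class FrameError(PsgscanError):
    """Internal stop codon or other reading-frame violation."""


class InsufficientTaxaError(PsgscanError):
    """Fewer than two species survive alignment filters."""


class InsufficientSetError(PsgscanError):
    pass


class FitError(PsgscanError):
    """Optimizer failed on every restart; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ParseError(PsgscanError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class NormalizationError(PsgscanError):
    pass


class UnknownTermError(PsgscanError, KeyError):
    pass
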