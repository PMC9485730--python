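"""Exception hierarchy used across the pipeline."""


class IrLncPairError(Exception):
    """Base class for all package errors."""


class FormatError(IrLncPairError):
    """A file does not follow the expected dialect (TSV/series-matrix/GMT)."""


class ParseError(FormatError):
    """A cell could not be parsed; carries row/column context in the message."""


class ValidationError(IrLncPairError, ValueError):
    """Input violates a documented precondition or controlled vocabulary."""


class ConfigurationError(ValidationError):
    """A simulation or pipeline configuration is internally inconsistent."""


class DegeneratePredictorError(ValidationError):
    """A model predictor is constant (or otherwise carries no information)."""


class SingularInformationError(IrLncPairError):
    """The Cox information matrix is singular; names the offending variables."""

    def __init__(self, variables, message=None):
        self.variables = list(variables)
        super().__init__(
            message or f"collinear predictors: {', '.join(self.variables)}"
        )


class DegenerateStratificationError(ValidationError):
    """All risk scores identical; no high/low split exists."""
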