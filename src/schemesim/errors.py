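"""Exception hierarchy shared across the package."""

from __future__ import annotations


class SchemeError(Exception):
    """Base class for all schemesim errors."""


class SchemeValidationError(SchemeError):
    """A scheme failed structural validation; carries the diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(str(d) for d in self.diagnostics)
        super().__init__(f"scheme validation failed: {lines}")


class ExpressionError(SchemeError):
    """Base class for expression language errors."""


class ExpressionSyntaxError(ExpressionError):
    def __init__(self, message, source, position):
        self.source = source
        self.position = position
        super().__init__(f"{message} at position {position} in {source!r}")


class ExpressionEvalError(ExpressionError):
    """Unbound symbol or arithmetic domain error during evaluation."""


class DerivationError(SchemeError):
    """Mass-balance derivation failed (bad symbol, rule conflict, ...)."""


class IntegrationError(SchemeError):
    """The stiff solver failed; ``last_time`` is the last successful time."""

    def __init__(self, message, last_time=None):
        self.last_time = last_time
        super().__init__(message)


class ModelFormatError(SchemeError):
    """Malformed native JSON model document."""


class TimeCourseFormatError(SchemeError):
    """Malformed time-course CSV file."""


class SBMLImportError(SchemeError):
    """The SBML document could not be read at all."""


class UnsupportedSBMLError(SchemeError):
    """The SBML document uses constructs outside the supported subset.

    ``features`` names every offending construct (e.g. "csymbol delay").
    """

    def __init__(self, features):
        self.features = list(features)
        super().__init__(
            "unsupported SBML feature(s): " + ", ".join(self.features)
        )


class EstimationError(SchemeError):
    """Ill-posed estimation problem (bounds, unknown parameter, ...)."""
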