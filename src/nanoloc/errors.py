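"""Exception hierarchy shared across the pipeline."""


class NanolocError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(NanolocError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class ParseError(NanolocError, ValueError):
    """A localization table file could not be parsed."""


class DriftDomainError(NanolocError, ValueError):
    """A frame falls outside the domain of a drift model."""


class FitFailureError(NanolocError, RuntimeError):
    """An optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateFitError(NanolocError, ValueError):
    """A mixture fit collapsed onto (effectively) a single component."""


class UndefinedStatisticError(NanolocError, ValueError):
    """A statistic is undefined for the given input (e.g. no consecutive pair)."""
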