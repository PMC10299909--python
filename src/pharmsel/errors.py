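"""Exception hierarchy shared across pharmsel modules."""


class PharmselError(Exception):
    """Base class for all pharmsel errors."""


class ValidationError(PharmselError, ValueError):
    """A spec/table/configuration invariant was violated; message names it."""


class DomainError(PharmselError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DataError(PharmselError):
    """Malformed input data (bad cell, missing column, non-monotone time)."""


class FitFailure(PharmselError):
    """A nonlinear fit did not converge or the data are degenerate.

    Carries a ``diagnostics`` dict (residuals, optimizer status, data
    summaries) so failures are explicit, never silent defaults.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SolverError(PharmselError):
    """Equilibrium solver failed to reach the requested residual."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals
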