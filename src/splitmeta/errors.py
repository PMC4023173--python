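"""Exception and warning types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when inputs violate a documented precondition."""


class TrialDataError(InvalidInputError):
    """Raised when a trial CSV fails validation.

    Carries per-row diagnostics in :attr:`row_errors`, a list of
    ``(line_number, message)`` pairs (1-based line numbers including the
    header line).
    """

    def __init__(self, message: str, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])


class ConvergenceError(RuntimeError):
    """Raised when an iterative estimator fails to converge.

    The last iterate is carried in :attr:`last_value` so callers can
    inspect how far the solver got.
    """

    def __init__(self, message: str, last_value: float):
        super().__init__(message)
        self.last_value = last_value


class FeasibilityWarning(UserWarning):
    """A requested correlation was clamped to the feasible region."""
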