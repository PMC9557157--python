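"""Package-wide exception types."""


class ParameterError(ValueError):
    """A model parameter or option is outside its admissible range."""


class ConvergenceError(RuntimeError):
    """An iterative computation failed to reach its stopping criterion.

    Carries a ``residual`` attribute with the last measured residual so
    callers can report how far the run was from convergence.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class SolverError(RuntimeError):
    """The flow solver violated one of its runtime contracts (CFL cap,
    pressure-solve failure)."""
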