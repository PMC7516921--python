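"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A distribution or model parameter violates its constraint."""


class BinningError(ValueError):
    """A histogram/binning request cannot be satisfied (too few points)."""


class DegenerateFitError(ValueError):
    """Residuals have zero spread, so log-based criteria are undefined."""


class ConvergenceError(RuntimeError):
    """An iterative fit did not converge within its iteration budget."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
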