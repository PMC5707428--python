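"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition or type invariant."""


class ParseError(ValueError):
    """A curve table or configuration file could not be parsed."""


class EngineError(RuntimeError):
    """An external forward-model engine failed (missing, crashed, or bad output)."""


class DegenerateLikelihoodError(RuntimeError):
    """Every prior sample has zero likelihood; tempering cannot start."""


class NonConvergenceError(RuntimeError):
    """The tempering schedule did not reach exponent 1 within ``max_stages``.

    Carries the partial ensemble state for post-mortem inspection.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class PredictionError(RuntimeError):
    """Too many forward-model failures during posterior propagation."""
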