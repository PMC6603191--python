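"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class ParseError(ValueError):
    """A data file is malformed; the message names the offending line(s)."""


class EstimationError(RuntimeError):
    """A closed-form estimator cannot be evaluated on the given curve."""


class DiagnosticError(RuntimeError):
    """An MCMC chain or posterior summary failed a sanity check."""
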