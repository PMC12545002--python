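"""Exception hierarchy shared across the package."""


class CeusticError(Exception):
    """Base class for all package errors."""


class ValidationError(CeusticError):
    """Input violates a documented contract (bad shapes, empty ROI, ...)."""


class EstimationError(CeusticError):
    """A numerical estimation step cannot proceed (degenerate input)."""
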