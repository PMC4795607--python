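"""Shared exception and warning types."""


class DegenerateDataError(ValueError):
    """Raised when a sample admits no meaningful fit (e.g. all values zero)."""


class NotPSDError(ValueError):
    """Raised when a Gram matrix violates positive semidefiniteness
    beyond numerical tolerance."""


class FitNonConvergenceWarning(UserWarning):
    """Emitted when an iterative fit stops without meeting its tolerance."""


class KernelDomainWarning(UserWarning):
    """Emitted when a fractional-exponent polynomial kernel is evaluated on a
    negative base (non-Mercer region); the base is clamped at zero."""
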