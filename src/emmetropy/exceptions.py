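"""Exception hierarchy shared across the pipeline."""


class EmmetropyError(ValueError):
    """Base class for all pipeline errors."""


class InvalidSpecError(EmmetropyError):
    """A generator spec violates its invariants (non-positive duration, bad ordering...)."""


class InvalidInputError(EmmetropyError):
    """Analysis input violates its contract (non-monotone time, grid mismatch...)."""


class InsufficientDataError(EmmetropyError):
    """Too few observations to compute the requested quantity."""


class DegenerateDataError(EmmetropyError):
    """Input is formally valid but degenerate (all-zero profile, zero-width lens...)."""
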