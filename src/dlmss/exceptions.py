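"""Exception taxonomy shared across the package."""


class DlmssError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DlmssError, ValueError):
    """A numeric parameter is outside its valid domain."""


class ValidationError(DlmssError, ValueError):
    """A composite object (e.g. a transition matrix) fails its invariants."""


class TooShortError(DlmssError, ValueError):
    """A trajectory is too short for the requested operation."""


class DegenerateDataError(DlmssError, ValueError):
    """Input data carries no usable signal (single class, zero support...)."""


class LagError(DlmssError, ValueError):
    """A displacement lag is incompatible with the trajectory length."""


class CompatibilityError(DlmssError, ValueError):
    """A saved model artifact does not match the requested configuration."""


class FormatError(DlmssError, ValueError):
    """A trajectory table is malformed (missing columns, bad ordering...)."""


class ComparabilityError(DlmssError, ValueError):
    """Two summaries cannot be compared (mismatched class sets)."""
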