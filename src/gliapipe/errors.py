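"""Exception types raised across the pipeline."""


class GliaPipeError(Exception):
    """Base class for all package-specific errors."""


class DegenerateHistogramError(GliaPipeError):
    """A threshold method was asked to split a constant-valued channel."""


class PlacementError(GliaPipeError):
    """Synthetic scene could not place all cells without overlap."""


class ParameterError(GliaPipeError, ValueError):
    """An operation received inconsistent parameters."""


class UnbalancedDesignError(GliaPipeError):
    """A factorial design cell is empty; names the offending cell."""


class UndefinedCorrelationError(GliaPipeError):
    """Correlation requested on a zero-variance sample."""


class ManifestError(GliaPipeError):
    """An image cannot be mapped to an animal, or manifest rows conflict."""
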