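"""Exception hierarchy shared across the pipeline stages."""


class PinyonError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PinyonError, ValueError):
    """Invalid configuration (degenerate ranges, missing coefficients, bad factors)."""


class DataError(PinyonError, ValueError):
    """Invalid data content (nodata at sampled cells, degenerate features, empty tables)."""


class SamplingError(PinyonError, ValueError):
    """A stratum cannot supply the requested number of sample cells."""


class EstimationError(PinyonError, ValueError):
    """A design-based estimator is undefined for the given error matrix."""


class FitError(PinyonError, RuntimeError):
    """A model fit failed (separation, rank deficiency, non-convergence)."""
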