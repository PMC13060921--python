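"""Exception hierarchy shared across the package."""


class DjdoseError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(DjdoseError):
    """An interval falls outside its declared sequence."""


class ConfigurationError(DjdoseError):
    """Required inputs (chromosome entries, lengths, paths) are missing."""


class UndefinedEstimateError(DjdoseError):
    """A copy-number denominator is zero; the estimate is undefined."""


class CalibrationError(DjdoseError):
    """The k-mer spectrum has no usable diploid peak."""


class DegenerateDesignError(DjdoseError):
    """Regression design matrix is rank-deficient (constant predictor)."""


class MixtureFitError(DjdoseError):
    """EM produced a non-finite likelihood or too many bootstrap failures."""
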