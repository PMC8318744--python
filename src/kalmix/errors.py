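"""Exception hierarchy shared across the package."""


class KalmixError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(KalmixError):
    """A spectrum file could not be parsed."""


class GridMismatchError(KalmixError):
    """Spectra do not share a common wavelength grid."""


class UnobservableComponentError(KalmixError):
    """A calibration standard carries no signal for its component."""


class SingularityError(KalmixError):
    """The sensitivity matrix is rank-deficient (collinear components)."""


class NumericalStabilityError(KalmixError):
    """The filter covariance lost positive semi-definiteness."""


class ConfigError(KalmixError):
    """A configuration file or design description is invalid."""
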