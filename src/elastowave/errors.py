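"""Exception and warning types shared across the package."""


class ElastoWaveError(Exception):
    """Base class for all package errors."""


class ParameterError(ElastoWaveError, ValueError):
    """A numeric argument is outside its physical or statistical domain."""


class ConfigurationError(ElastoWaveError, ValueError):
    """Required modality metadata (wavelength, center frequency, ...) is missing
    or inconsistent with the requested operation."""


class EstimationError(ElastoWaveError, RuntimeError):
    """An estimator could not produce a valid result (e.g. non-positive
    time-of-flight slope on both propagation sides)."""


class AliasingWarning(UserWarning):
    """Inter-frame displacement approached the unambiguous phase range."""


class LowSNRWarning(UserWarning):
    """Phase statistics are consistent with pure noise; the returned field is
    unlikely to contain a usable wave signal."""
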