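"""Exception hierarchy for the dermaflim pipeline.

All pipeline errors derive from :class:`DermaflimError` so callers can catch
the whole family; each stage raises the most specific subclass it can.
"""


class DermaflimError(Exception):
    """Base class for all dermaflim errors."""


class ConfigurationError(DermaflimError, ValueError):
    """A parameter value is outside its valid range or inconsistent."""


class ValidationError(DermaflimError, ValueError):
    """Input data fails a structural or range check."""


class BelowThresholdError(DermaflimError):
    """A decay trace carries too few photons for a reliable fit."""


class EmptyMapError(DermaflimError):
    """Every pixel of a lifetime map is masked; the frame is unusable."""


class InsufficientDataError(DermaflimError):
    """Fewer valid observations than the statistic requires."""


class UndefinedValueError(DermaflimError, ZeroDivisionError):
    """A derived quantity is undefined for this input (e.g. a1 + a2 = 0)."""


class DegenerateSpectrumError(DermaflimError):
    """The medium-frequency annulus of the spectrum has zero mean magnitude."""


class DegenerateFeatureError(DermaflimError):
    """A feature column has zero variance and cannot be standardized."""


class DegenerateRatioError(DermaflimError):
    """A paired-site ratio has a zero denominator."""


class InconsistentLayersError(DermaflimError):
    """Selected SG depth is not strictly shallower than the SB depth."""


class IncompleteSubjectError(DermaflimError):
    """A subject/site is missing a constituent feature and must be excluded."""


class SchemaMismatchError(DermaflimError, KeyError):
    """A feature vector does not match the model's feature schema."""


class FormatError(DermaflimError, IOError):
    """An on-disk file does not follow the expected layout."""


class OutOfCohortRangeWarning(UserWarning):
    """A clinical score lies outside the range the banding was defined on."""
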