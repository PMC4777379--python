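"""Exception hierarchy shared across the pipeline stages."""


class PhysioAffectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhysioAffectError, ValueError):
    """Invalid study design, filter or pipeline configuration."""


class SamplingRateError(ConfigurationError):
    """Sampling rate incompatible with the requested filter band."""


class SignalQualityError(PhysioAffectError, ValueError):
    """Signal too degraded to extract the requested physiology (e.g. < 3 beats)."""


class AlignmentError(PhysioAffectError, ValueError):
    """Event timeline does not fit the recording (block or baseline out of range)."""


class InsufficientDataError(PhysioAffectError, ValueError):
    """Too few samples, beats, blocks or subjects for the statistic."""


class CompletenessError(PhysioAffectError, ValueError):
    """A (subject, block) is missing one or more features."""
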