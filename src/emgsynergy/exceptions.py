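"""Exception hierarchy shared across the pipeline stages."""


class SynergyError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SynergyError, ValueError):
    """An argument is outside its documented valid range."""


class EventDetectionError(SynergyError):
    """No usable events could be found in a click/metronome signal."""


class EpochingError(SynergyError):
    """Event-locked windowing produced no valid cycles."""


class NormalizationError(SynergyError):
    """A muscle channel cannot be normalized (e.g. constant signal)."""


class FormatError(SynergyError, ValueError):
    """A delimited input file does not match the expected layout."""
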