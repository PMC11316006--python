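"""Exception hierarchy for the pipeline."""


class EMGSleeveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EMGSleeveError):
    """Invalid or inconsistent configuration (layouts, filters, mappings)."""


class ScheduleError(EMGSleeveError):
    """Invalid cue-schedule construction request."""


class AlignmentError(EMGSleeveError):
    """Label/bin-clock alignment failure."""


class FittingError(EMGSleeveError):
    """Model or scaler fitting failure."""


class StreamingError(EMGSleeveError):
    """Streaming inference contract violation."""


class MetricError(EMGSleeveError):
    """Undefined or ill-posed evaluation metric request."""
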