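"""Exception hierarchy for xsilence."""


class XSilenceError(Exception):
    """Base class for all xsilence errors."""


class FormatError(XSilenceError, ValueError):
    """A file or table violates the expected format (duplicate ids, negative
    intensities, missing columns, ...)."""


class ConfigurationError(XSilenceError, ValueError):
    """A configuration value is invalid; the message names the field."""


class AnalysisError(XSilenceError, ValueError):
    """An analysis-stage precondition is violated (empty chromosome class,
    disjoint probe universes, too few replicates, ...)."""


class PipelineError(XSilenceError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
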