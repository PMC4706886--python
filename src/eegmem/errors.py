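"""Exception hierarchy shared by all pipeline stages."""


class EEGMemError(Exception):
    """Base class for all package errors."""


class FormatError(EEGMemError, ValueError):
    """A file could not be parsed in the declared format."""


class ConsistencyError(EEGMemError, ValueError):
    """Two inputs that must agree (shapes, channel lists, masks) do not."""


class RangeError(EEGMemError, ValueError):
    """A sample interval is empty, inverted, or outside the recording."""


class LabelError(EEGMemError, ValueError):
    """A class label is outside {0, 1}."""


class UniquenessError(EEGMemError, ValueError):
    """An identifier that must be unique is duplicated."""


class ChannelLookupError(EEGMemError, KeyError):
    """A channel id is not present in the recording or layout."""


class QuestionLookupError(EEGMemError, KeyError):
    """A question id is not present in the event table."""


class ParameterError(EEGMemError, ValueError):
    """A parameter is outside its documented range."""


class LayoutError(EEGMemError, ValueError):
    """An electrode layout is degenerate (fewer than 3 non-collinear points)."""


class DegenerateInputError(EEGMemError, ValueError):
    """An input is too small for the operation (e.g. a 1-map sequence)."""


class InputError(EEGMemError, ValueError):
    """A data input violates an operation precondition (empty class, ...)."""


class PipelineStageError(EEGMemError, RuntimeError):
    """Wraps a failure inside the pipeline, naming the failing stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
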