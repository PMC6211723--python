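"""Exception hierarchy for the cover-test pipeline."""


class CoverTestError(Exception):
    """Base class for all package errors."""


class GazeFormatError(CoverTestError):
    """A gaze file violates the expected text format."""


class ColumnMappingError(CoverTestError):
    """The column-mapping config cannot be applied to the input table."""


class ScheduleError(CoverTestError):
    """A phase or schedule does not fit the recording."""


class ParameterError(CoverTestError):
    """An operation was called with out-of-range parameters."""
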