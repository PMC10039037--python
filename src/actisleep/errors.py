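"""Exception hierarchy for actisleep."""


class ActisleepError(Exception):
    """Base class for all actisleep errors."""


class FormatError(ActisleepError):
    """A file does not conform to the expected delimited-text contract."""


class DataError(ActisleepError):
    """File parsed but its content violates a precondition (e.g. non-monotone time)."""


class GapError(DataError):
    """Recording contains internal gaps larger than twice the sample interval."""

    def __init__(self, message: str, gap_indices=None):
        super().__init__(message)
        self.gap_indices = list(gap_indices) if gap_indices is not None else []


class ParameterError(ActisleepError):
    """An operation was called with invalid or inconsistent parameters."""


class AlignmentError(ActisleepError):
    """Two epoch series do not overlap, or a signal does not cover a grid."""


class TrainingError(ActisleepError):
    """Model training received unusable labels (e.g. a single class)."""
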