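"""Exception hierarchy for tspc4."""


class TSPC4Error(Exception):
    """Base class for all tspc4 errors."""


class SequenceParseError(TSPC4Error):
    """Raised when a sequence or repeat notation cannot be interpreted."""


class FileFormatError(TSPC4Error):
    """Raised when a structure/trajectory/table file violates its format."""


class SelectionError(TSPC4Error):
    """Raised when an atom selection resolves to nothing or is inconsistent."""


class AnalysisError(TSPC4Error):
    """Raised when a statistic cannot be computed from the given inputs."""


class NoTransitionError(AnalysisError):
    """Raised when a melt curve shows no detectable unfolding transition."""
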