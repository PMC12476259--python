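"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration/parameter problems -> 2,
data/I-O problems -> 3, convergence or degenerate-result problems -> 4.
"""


class HolosegError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(HolosegError):
    """Invalid configuration: unknown keys, bad values, overlapping intervals."""

    exit_code = 2


class ParameterError(HolosegError):
    """An operation was called with out-of-contract arguments."""

    exit_code = 2


class StateError(HolosegError):
    """An operation was applied to an object in the wrong state (e.g. wrong color space)."""

    exit_code = 2


class DataError(HolosegError):
    """Unreadable, truncated or structurally invalid input data."""

    exit_code = 3


class FormatError(DataError):
    """Unsupported image format or channel count."""

    exit_code = 3


class DegenerateInputError(HolosegError):
    """Input admits no meaningful answer (e.g. constant amplitude map has no peak)."""

    exit_code = 4


class DegenerateResultError(HolosegError):
    """A computation collapsed to a degenerate result (e.g. empty segmentation)."""

    exit_code = 4


class ConvergenceError(HolosegError):
    """Iterative optimisation diverged; carries the last stable state when available."""

    exit_code = 4

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class FitError(HolosegError):
    """Interval fitting produced overlapping class intervals."""

    exit_code = 2
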