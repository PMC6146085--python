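"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (I/O and format problems,
geometry/topology problems, insufficient data).
"""


class ChestwallError(Exception):
    """Base class for all package errors."""


class FormatError(ChestwallError):
    """A trajectory or layout file could not be parsed."""


class UnsupportedFormatError(FormatError):
    """A file format the package does not read/write was requested."""


class LayoutMismatchError(ChestwallError):
    """Marker names in a file do not match the declared layout."""


class GeometryError(ChestwallError):
    """Degenerate or inconsistent marker geometry."""


class TopologyError(GeometryError):
    """A surface mesh is not closed/consistently oriented."""


class InsufficientDataError(ChestwallError):
    """The recording is too short for the requested analysis."""


class InsufficientBreathsError(InsufficientDataError):
    """Fewer complete breaths than required were found."""


class UndefinedCorrelationError(ChestwallError):
    """Rank correlation is undefined (constant input vector)."""


class StageError(ChestwallError):
    """Pipeline failure annotated with the stage and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        super().__init__(f"[{subject_id}] stage '{stage}' failed: {cause}")
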