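"""Exception hierarchy shared across the pipeline."""


class PalmcellError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PalmcellError):
    """A required column or field is missing from an input file."""


class ParseError(PalmcellError):
    """A cell in an input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"{message} (line {line})")


class FormatError(PalmcellError):
    """The file is not in the expected container format (e.g. not a TIFF)."""


class ParameterError(PalmcellError):
    """An operation received an out-of-range or incomplete parameter."""


class GenerationError(PalmcellError):
    """A synthetic scene specification cannot be realized."""


class CoverageError(PalmcellError):
    """A drift model or transform does not cover the requested frames/points."""


class GapError(PalmcellError):
    """A frame has no valid fiducial observation; carries the frame index."""

    def __init__(self, message: str, frame: int | None = None):
        self.frame = frame
        super().__init__(message)


class InsufficientBeadsError(PalmcellError):
    """Fewer matched fiducial pairs than the fit requires."""


class DegeneracyError(PalmcellError):
    """The fit design matrix is rank-deficient (e.g. collinear beads)."""


class AmbiguityError(PalmcellError):
    """A cluster centroid lies inside more than one cell contour."""


class StageError(PalmcellError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
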