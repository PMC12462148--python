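"""Exception hierarchy for the rootalign toolkit.

Every failure mode the pipeline can hit is a distinct subclass so callers
(and the CLI) can report which stage failed without string matching.
"""


class RootAlignError(Exception):
    """Base class for all rootalign errors."""


class ContractViolationError(RootAlignError):
    """An operation was called with input violating its stated precondition."""


class GeometryError(RootAlignError):
    """A box or ROI does not intersect the volume grid, or an object does not fit."""


class FormatError(RootAlignError):
    """An annotation file is malformed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptySelectionError(RootAlignError):
    """Thresholding (or component selection) produced no voxels.

    Carries the threshold that was used so callers can diagnose an
    over-aggressive setting.
    """

    def __init__(self, message: str, threshold: float | None = None, stage: str = ""):
        self.threshold = threshold
        self.stage = stage
        super().__init__(message)


class DegenerateComponentError(RootAlignError):
    """Too few voxels (or rank-deficient geometry) for axis estimation."""

    def __init__(self, message: str, stage: str = ""):
        self.stage = stage
        super().__init__(message)


class AmbiguousAxisError(RootAlignError):
    """The two leading PCA eigenvalues tie; the principal axis is not unique."""


class UndefinedAPError(RootAlignError):
    """Average precision is undefined because there are no ground-truth boxes."""


class InsufficientDataError(RootAlignError):
    """Fewer paired measurements than the agreement statistics require."""
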