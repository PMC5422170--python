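"""Exception hierarchy for the paddyid pipeline."""


class PaddyIdError(Exception):
    """Base class for all pipeline errors."""


class DegenerateHistogramError(PaddyIdError):
    """Raised when Otsu thresholding is attempted on a constant image."""


class NoForegroundError(PaddyIdError):
    """Raised when a binary mask that must contain a seed is empty."""


class ContourError(PaddyIdError):
    """Raised when contour tracing preconditions are violated."""


class ConcavityError(PaddyIdError):
    """Raised when the two chaff-tip concavities cannot be located."""


class GeometryError(PaddyIdError):
    """Raised for degenerate geometric configurations, tagged with the stage."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message if stage is None else f"[{stage}] {message}")
        self.stage = stage


class SyntheticError(PaddyIdError):
    """Raised when a synthetic silhouette construction is invalid."""
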