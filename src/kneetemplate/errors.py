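"""Exception hierarchy for the templating pipeline.

Every stage raises a named subclass of :class:`TemplatingError` so callers
(and the CLI) can attach view/component context without string matching.
"""


class TemplatingError(Exception):
    """Base class for all pipeline errors."""


class DegenerateMarkerError(TemplatingError):
    """Calibration marker endpoints coincide."""


class DegenerateAxisError(TemplatingError):
    """Two landmarks that should define an axis coincide."""


class DegenerateFitError(TemplatingError):
    """Too few points to fit a line (anterior cortical line)."""


class MissingLandmarkError(TemplatingError):
    """A required named landmark is absent from the scene."""

    def __init__(self, name: str, view: str = ""):
        self.name = name
        self.view = view
        super().__init__(f"missing required landmark {name!r}"
                         + (f" for view {view}" if view else ""))


class MissingContourError(TemplatingError):
    """A required bone contour is absent from the scene."""


class ResectionMissesBoneError(TemplatingError):
    """A resection line intersects the bone contour fewer than twice."""


class ConfigurationError(TemplatingError):
    """Invalid size chart or other configuration."""


class GenerationError(TemplatingError):
    """Synthetic-anatomy parameters produced an invalid contour."""


class UnderdeterminedTransformError(TemplatingError):
    """Fewer than two point pairs for similarity-transform fitting."""


class UndefinedKappaError(TemplatingError):
    """Weighted kappa undefined: no expected disagreement mass."""


class EmptyMaskError(TemplatingError):
    """A bone mask raster contains no foreground pixels."""


class StageError(TemplatingError):
    """Wraps a component failure with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
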