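"""The calibrated per-view scene container consumed by all templating steps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import Calibration
from .errors import MissingContourError, MissingLandmarkError, TemplatingError
from .geometry import ContourPolygon, Point2

__all__ = ["KneeScene", "REQUIRED_LANDMARKS", "REQUIRED_CONTOURS"]

REQUIRED_LANDMARKS = {
    "AP": ("femoral_head_center", "trochlear_groove",
           "tibial_plateau_medial", "tibial_plateau_lateral",
           "talar_dome_center"),
    "LAT": ("plateau_anterior", "plateau_posterior",
            "tibial_shaft_proximal", "tibial_shaft_distal"),
}

REQUIRED_CONTOURS = {
    "AP": ("femur", "tibia"),
    "LAT": ("femur", "tibia", "patella", "fibula"),
}


@dataclass
class KneeScene:
    """One view's calibrated bone contours and named landmarks.

    Coordinates are in millimetres with y increasing proximally.  ``view``
    is ``"AP"`` (coronal, full leg) or ``"LAT"`` (sagittal knee); ``side``
    is ``"left"`` or ``"right"``.
    """

    view: str
    side: str
    contours: dict[str, ContourPolygon]
    landmarks: dict[str, Point2]
    calibration: Calibration
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.view not in ("AP", "LAT"):
            raise TemplatingError(f"unknown view {self.view!r}")
        if self.side not in ("left", "right"):
            raise TemplatingError(f"unknown side {self.side!r}")

    def validate(self) -> "KneeScene":
        """Check required landmarks and contours for this view are present."""
        for name in REQUIRED_LANDMARKS[self.view]:
            if name not in self.landmarks:
                raise MissingLandmarkError(name, self.view)
        for name in REQUIRED_CONTOURS[self.view]:
            if name not in self.contours:
                raise MissingContourError(
                    f"missing required contour {name!r} for view {self.view}")
        return self

    def landmark(self, name: str) -> Point2:
        try:
            return self.landmarks[name]
        except KeyError:
            raise MissingLandmarkError(name, self.view) from None

    def contour(self, name: str) -> ContourPolygon:
        try:
            return self.contours[name]
        except KeyError:
            raise MissingContourError(
                f"missing required contour {name!r} for view {self.view}") from None

    def transformed(self, matrix: np.ndarray, shift: np.ndarray) -> "KneeScene":
        """Apply an affine map (rigid motion in practice) to all geometry."""
        matrix = np.asarray(matrix, dtype=float)
        shift = np.asarray(shift, dtype=float)
        contours = {k: c.transformed(matrix, shift) for k, c in self.contours.items()}
        landmarks = {
            k: Point2.from_array(matrix @ p.array + shift)
            for k, p in self.landmarks.items()
        }
        return KneeScene(view=self.view, side=self.side, contours=contours,
                         landmarks=landmarks, calibration=self.calibration,
                         meta=dict(self.meta))
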