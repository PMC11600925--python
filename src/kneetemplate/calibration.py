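"""Pixel-to-millimetre calibration from a marker of known physical size.

Radiographs magnify objects by a source-to-detector dependent factor; a
ruler or sphere of known size placed at bone level gives a single isotropic
scale per image.  Marker endpoints are provided as input (detecting them in
the raw image is the job of an upstream recognizer, not this package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateMarkerError, TemplatingError
from .geometry import ContourPolygon, Point2

__all__ = ["CalibrationMarker", "Calibration", "PixelScene",
           "compute_scale", "calibrate_scene", "scene_to_pixel"]


@dataclass(frozen=True)
class CalibrationMarker:
    """Two pixel points whose physical separation is known in millimetres."""

    p1: Point2
    p2: Point2
    known_separation_mm: float

    def __post_init__(self):
        if self.known_separation_mm <= 0:
            raise TemplatingError("marker separation must be positive")


@dataclass(frozen=True)
class Calibration:
    """Isotropic image scale in millimetres per pixel."""

    mm_per_pixel: float

    def __post_init__(self):
        if not (self.mm_per_pixel > 0 and math.isfinite(self.mm_per_pixel)):
            raise TemplatingError("mm_per_pixel must be positive and finite")


@dataclass
class PixelScene:
    """A scene still in the raster frame: pixel coordinates, y down.

    Produced by :func:`kneetemplate.io.read_scene`; converted to the
    calibrated millimetre frame (y up) by :func:`calibrate_scene`.
    """

    view: str
    side: str
    contours: dict[str, np.ndarray]          # name -> (n, 2) pixel (x, y)
    landmarks: dict[str, Point2]             # pixel frame
    marker: CalibrationMarker
    image_height_px: int
    extras: dict = field(default_factory=dict)


def compute_scale(marker: CalibrationMarker) -> Calibration:
    """mm/pixel from the marker's pixel length and known physical length."""
    d = marker.p1.distance_to(marker.p2)
    if d < 1e-9:
        raise DegenerateMarkerError("calibration marker endpoints coincide")
    return Calibration(marker.known_separation_mm / d)


def calibrate_scene(pixel_scene: PixelScene):
    """Convert a pixel-frame scene to the calibrated mm frame.

    The raster y axis points down; the calibrated frame has y increasing
    proximally, so rows are flipped about the image height:
    ``x_mm = x_px * s`` and ``y_mm = (H - y_px) * s``.
    """
    from .scene import KneeScene  # deferred: scene depends on calibration

    cal = compute_scale(pixel_scene.marker)
    s = cal.mm_per_pixel
    h = float(pixel_scene.image_height_px)

    contours = {}
    for name, v in pixel_scene.contours.items():
        v = np.asarray(v, dtype=float).reshape(-1, 2)
        mm = np.column_stack([v[:, 0] * s, (h - v[:, 1]) * s])
        contours[name] = ContourPolygon(mm)
    landmarks = {
        name: Point2(p.x * s, (h - p.y) * s)
        for name, p in pixel_scene.landmarks.items()
    }
    return KneeScene(view=pixel_scene.view, side=pixel_scene.side,
                     contours=contours, landmarks=landmarks, calibration=cal)


def scene_to_pixel(scene, cal: Calibration, image_height_px: int) -> PixelScene:
    """Inverse of :func:`calibrate_scene` at a chosen scale and canvas height.

    Used to write synthetic scenes in the raster dialect and to verify
    magnification invariance: the marker is synthesized along the x axis so
    that re-calibration recovers exactly ``cal``.
    """
    s = cal.mm_per_pixel
    h = float(image_height_px)
    contours = {
        name: np.column_stack([c.vertices[:, 0] / s, h - c.vertices[:, 1] / s])
        for name, c in scene.contours.items()
    }
    landmarks = {
        name: Point2(p.x / s, h - p.y / s)
        for name, p in scene.landmarks.items()
    }
    marker = CalibrationMarker(Point2(0.0, 0.0), Point2(100.0, 0.0),
                               known_separation_mm=100.0 * s)
    return PixelScene(view=scene.view, side=scene.side, contours=contours,
                      landmarks=landmarks, marker=marker,
                      image_height_px=image_height_px)
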