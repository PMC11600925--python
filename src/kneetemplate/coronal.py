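"""Coronal-plane templating: mechanical axes, resection lines, ML widths.

The coronal plan follows mechanical alignment with a neutral hip-knee-ankle
(HKA) target.  The femoral mechanical axis (FMA) runs from the femoral head
center to the trochlear groove; the tibial mechanical axis (TMA) from the
midpoint of the tibial plateau edges to the talar dome center.  The femoral
cut is placed 9 mm proximal to the most distal condyle (the implant's distal
thickness) perpendicular to the FMA; the tibial cut 10 mm distal to the
highest plateau point perpendicular to the TMA (medial proximal tibial
angle, MPTA, of 90 deg).  When bone attrition or varus deformity leaves the
lesser side with under 2 mm of resection, the tibial cut is tilted 2 deg
(MPTA 88 deg) toward deeper resection on that side and re-measured.

The outermost intersections of each resection line with the bone contour
are the medial/lateral insert points; their separation is the mediolateral
(ML) width used for size selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateAxisError, ResectionMissesBoneError, StageError)
from .geometry import (ContourPolygon, DirectedLine, Point2, angle_between_deg,
                       furthest_point_along, line_polygon_intersections,
                       perpendicular_line_at, project_offsets,
                       rotate_line_about)
from .scene import KneeScene

__all__ = ["CoronalPlan", "femoral_mechanical_axis", "tibial_mechanical_axis",
           "femoral_coronal_sizing", "tibial_coronal_sizing",
           "coronal_template"]


@dataclass
class CoronalPlan:
    fma: DirectedLine
    tma: DirectedLine
    femoral_resection: DirectedLine
    tibial_resection: DirectedLine
    femoral_insert_points: tuple[Point2, Point2]   # (medial, lateral)
    tibial_insert_points: tuple[Point2, Point2]    # (medial, lateral)
    femoral_ml_width: float
    tibial_ml_width: float
    mpta_deg: float
    hka_deg: float                                  # varus positive
    lesser_side_depth_mm: float
    lesser_side: str                                # "medial" | "lateral"
    mpta_adjusted: bool


def femoral_mechanical_axis(scene: KneeScene) -> DirectedLine:
    """FMA through femoral head center and trochlear groove, directed distally."""
    head = scene.landmark("femoral_head_center")
    groove = scene.landmark("trochlear_groove")
    return DirectedLine.through(head, groove)


def tibial_mechanical_axis(scene: KneeScene) -> DirectedLine:
    """TMA from the plateau-edge midpoint to the talar dome, directed distally."""
    med = scene.landmark("tibial_plateau_medial")
    lat = scene.landmark("tibial_plateau_lateral")
    talus = scene.landmark("talar_dome_center")
    mid = Point2((med.x + lat.x) / 2.0, (med.y + lat.y) / 2.0)
    return DirectedLine.through(mid, talus)


def _medial_unit(scene: KneeScene) -> np.ndarray:
    """Unit vector pointing medially, from the plateau landmark pair."""
    med = scene.landmark("tibial_plateau_medial")
    lat = scene.landmark("tibial_plateau_lateral")
    v = med.array - lat.array
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateAxisError("plateau landmarks coincide")
    return v / n


def _outermost_pair(line: DirectedLine, contour: ContourPolygon,
                    what: str) -> tuple[Point2, Point2]:
    """Outermost crossings of a resection line with a bone contour.

    Concave contours (osteophyte lobes, the intercondylar notch) can yield
    more than two crossings; the insert points are the cortical borders,
    i.e. the outermost pair along the line.
    """
    pts = line_polygon_intersections(line, contour)
    if len(pts) < 2:
        raise ResectionMissesBoneError(
            f"{what}: resection line crosses bone contour "
            f"{len(pts)} time(s); need at least 2")
    return pts[0], pts[-1]


def _label_medial_lateral(pair: tuple[Point2, Point2],
                          medial_hat: np.ndarray) -> tuple[Point2, Point2]:
    a, b = pair
    if float(np.dot(b.array - a.array, medial_hat)) >= 0:
        return b, a
    return a, b


def femoral_coronal_sizing(scene: KneeScene, fma: DirectedLine,
                           resection_mm: float = 9.0):
    """Place the femoral distal cut and measure its ML width.

    The most distal condylar point (extreme projection on the FMA) is
    translated ``resection_mm`` proximally along the axis; the perpendicular
    there is the resection line, and its outermost crossings with the femur
    contour are the insert points.

    Returns ``(resection_line, (medial, lateral) insert points, ml_width)``.
    """
    femur = scene.contour("femur")
    offs = project_offsets(femur.vertices, fma)
    t_distal = float(np.max(offs))          # fma directed distally
    station = t_distal - resection_mm       # back proximally
    resection = perpendicular_line_at(fma, station)
    pair = _outermost_pair(resection, femur, "femoral coronal")
    medial, lateral = _label_medial_lateral(pair, _medial_unit(scene))
    width = medial.distance_to(lateral)
    return resection, (medial, lateral), width


def _depth_along_axis(landmark: Point2, resection: DirectedLine,
                      axis: DirectedLine) -> float:
    """Resection depth at a plateau landmark, measured parallel to the axis.

    Positive when the resection line lies distal to the landmark (bone is
    removed); this is the travel from the landmark along the axis direction
    until the resection line is reached.
    """
    n = resection.normal
    denom = float(np.dot(axis.dir_array, n))
    if abs(denom) < 1e-12:
        raise DegenerateAxisError("resection line parallel to mechanical axis")
    return float(np.dot(resection.origin.array - landmark.array, n)) / denom


def _mpta(tma: DirectedLine, resection: DirectedLine,
          medial_hat: np.ndarray) -> float:
    """Medial proximal tibial angle: between the distal TMA direction and
    the medially-pointing resection direction (90 deg = perpendicular cut)."""
    r = resection.dir_array
    if float(np.dot(r, medial_hat)) < 0:
        r = -r
    c = float(np.clip(np.dot(tma.dir_array, r), -1.0, 1.0))
    return math.degrees(math.acos(c))


def tibial_coronal_sizing(scene: KneeScene, tma: DirectedLine,
                          offset_mm: float = 10.0,
                          min_lesser_depth_mm: float = 2.0,
                          adjusted_mpta_deg: float = 88.0):
    """Place the tibial cut, applying the lesser-side 2 mm depth rule.

    The cut starts perpendicular to the TMA, ``offset_mm`` distal to the
    most proximal plateau point.  The resection depth on each side is the
    axis-parallel distance from that side's plateau landmark down to the
    cut; if the lesser side gets under ``min_lesser_depth_mm``, the cut is
    rotated about its TMA crossing so the MPTA becomes ``adjusted_mpta_deg``
    with the tilt deepening the lesser side, then re-measured.

    Returns ``(resection, (medial, lateral) inserts, ml_width,
    lesser_side_depth, lesser_side, mpta_deg, adjusted)``.
    """
    tibia = scene.contour("tibia")
    med_lm = scene.landmark("tibial_plateau_medial")
    lat_lm = scene.landmark("tibial_plateau_lateral")
    medial_hat = _medial_unit(scene)

    offs = project_offsets(tibia.vertices, tma)
    t_prox = float(np.min(offs))            # tma directed distally
    station = t_prox + offset_mm
    resection = perpendicular_line_at(tma, station)

    def depths(line: DirectedLine) -> tuple[float, float]:
        return (_depth_along_axis(med_lm, line, tma),
                _depth_along_axis(lat_lm, line, tma))

    d_med, d_lat = depths(resection)
    lesser_side = "medial" if d_med <= d_lat else "lateral"
    lesser_depth = min(d_med, d_lat)
    adjusted = False

    if lesser_depth < min_lesser_depth_mm:
        tilt = 90.0 - adjusted_mpta_deg
        pivot = resection.intersect_line(tma)
        cand = [rotate_line_about(resection, pivot, sgn * tilt)
                for sgn in (+1.0, -1.0)]
        # tilt direction: the one that deepens the lesser side
        lm = med_lm if lesser_side == "medial" else lat_lm
        gains = [_depth_along_axis(lm, c, tma) for c in cand]
        resection = cand[int(np.argmax(gains))]
        d_med, d_lat = depths(resection)
        lesser_depth = d_med if lesser_side == "medial" else d_lat
        adjusted = True

    pair = _outermost_pair(resection, tibia, "tibial coronal")
    medial, lateral = _label_medial_lateral(pair, medial_hat)
    width = medial.distance_to(lateral)
    mpta = _mpta(tma, resection, medial_hat)
    return resection, (medial, lateral), width, lesser_depth, lesser_side, mpta, adjusted


def _signed_hka(fma: DirectedLine, tma: DirectedLine,
                medial_hat: np.ndarray) -> float:
    """HKA deviation between the axes; positive = varus.

    Varus is the bow-legged deformity: the tibial axis deviates medially
    relative to the femoral axis continuation at the knee.
    """
    f, t = fma.dir_array, tma.dir_array
    angle = math.degrees(math.acos(float(np.clip(np.dot(f, t), -1.0, 1.0))))
    perp = t - float(np.dot(t, f)) * f
    sign = 1.0 if float(np.dot(perp, medial_hat)) >= 0 else -1.0
    return sign * angle


def coronal_template(scene: KneeScene,
                     femur_resection_mm: float = 9.0,
                     tibia_offset_mm: float = 10.0,
                     min_lesser_depth_mm: float = 2.0,
                     adjusted_mpta_deg: float = 88.0) -> CoronalPlan:
    """Full coronal-plane pipeline on a calibrated AP scene."""
    scene.validate()
    try:
        fma = femoral_mechanical_axis(scene)
        tma = tibial_mechanical_axis(scene)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise StageError("coronal/axes", e) from e
    try:
        f_res, f_pts, f_ml = femoral_coronal_sizing(scene, fma, femur_resection_mm)
    except Exception as e:
        raise StageError("coronal/femoral_sizing", e) from e
    try:
        (t_res, t_pts, t_ml, lesser_depth, lesser_side,
         mpta, adjusted) = tibial_coronal_sizing(
            scene, tma, tibia_offset_mm, min_lesser_depth_mm, adjusted_mpta_deg)
    except Exception as e:
        raise StageError("coronal/tibial_sizing", e) from e

    hka = _signed_hka(fma, tma, _medial_unit(scene))
    return CoronalPlan(fma=fma, tma=tma, femoral_resection=f_res,
                       tibial_resection=t_res, femoral_insert_points=f_pts,
                       tibial_insert_points=t_pts, femoral_ml_width=f_ml,
                       tibial_ml_width=t_ml, mpta_deg=mpta, hka_deg=hka,
                       lesser_side_depth_mm=lesser_depth,
                       lesser_side=lesser_side, mpta_adjusted=adjusted)
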