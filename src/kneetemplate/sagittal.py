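"""Sagittal-plane templating: anterior cortical line, AP widths, tibial slope.

On the lateral view the femoral component is aligned to the anterior
cortical line of the distal femur (flushing the anterior flange to the
cortex avoids notching); the femoral AP length is the longest perpendicular
distance from that line to the distal femoral condyle.  The tibial
component is aligned to a posterior tibial slope (PTS, default 3 deg)
relative to the tibial anatomical axis, with the cut 10 mm distal to the
highest plateau point; the outermost crossings of the sloped cut with the
tibial contour are the anterior/posterior insert points and their distance
is the tibial AP width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, ResectionMissesBoneError, StageError
from .geometry import (ContourPolygon, DirectedLine, Point2,
                       line_polygon_intersections, perpendicular_line_at,
                       project_offsets, rotate_line_about)
from .scene import KneeScene

__all__ = ["SagittalPlan", "anterior_cortical_line", "femoral_sagittal_sizing",
           "tibial_anatomical_axis_sagittal", "tibial_sagittal_sizing",
           "sagittal_template"]


@dataclass
class SagittalPlan:
    anterior_cortical_line: DirectedLine
    femoral_ap_length: float
    femoral_posterior_point: Point2
    tibial_anatomical_axis: DirectedLine
    tibial_resection: DirectedLine
    tibial_ap_width: float
    tibial_insert_points: tuple[Point2, Point2]   # (anterior, posterior)
    pts_deg: float


def _posterior_unit(scene: KneeScene) -> np.ndarray:
    ant = scene.landmark("plateau_anterior")
    post = scene.landmark("plateau_posterior")
    v = post.array - ant.array
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateFitError("plateau anterior/posterior landmarks coincide")
    return v / n


def tibial_anatomical_axis_sagittal(scene: KneeScene) -> DirectedLine:
    """Axis through the proximal and distal tibial shaft landmarks, directed
    distally."""
    prox = scene.landmark("tibial_shaft_proximal")
    dist = scene.landmark("tibial_shaft_distal")
    return DirectedLine.through(prox, dist)


def _densify_boundary(vertices: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample a closed polygon boundary at roughly ``step`` mm spacing.

    Straight stretches of a simplified contour carry no interior vertices;
    scanline-based feature extraction needs boundary samples, not just
    corners.
    """
    pts = [vertices]
    closed = np.vstack([vertices, vertices[:1]])
    for a, b in zip(closed[:-1], closed[1:]):
        n = int(np.linalg.norm(b - a) / step)
        if n > 1:
            frac = np.arange(1, n)[:, None] / n
            pts.append(a + (b - a) * frac)
    return np.vstack(pts)


def anterior_cortical_line(scene: KneeScene, fit_window_mm: float = 60.0,
                           window_start_mm: float = 20.0,
                           bin_mm: float = 2.0) -> DirectedLine:
    """Total-least-squares fit to the anterior femoral shaft cortex.

    Boundary samples whose height above the most distal femoral point
    (measured along the tibial anatomical axis direction) falls in
    ``[window_start, window_start + fit_window]`` are binned into
    ``bin_mm`` scanline bands; the anterior-most sample of each band feeds
    a principal-axis fit.  The result is oriented distally.
    """
    femur = scene.contour("femur")
    axis = tibial_anatomical_axis_sagittal(scene)
    posterior_hat = _posterior_unit(scene)
    distal_hat = axis.dir_array                      # points distally
    proximal_hat = -distal_hat

    v = _densify_boundary(femur.vertices)
    heights = (v - v[int(np.argmax(v @ distal_hat))]) @ proximal_hat
    lo, hi = window_start_mm, window_start_mm + fit_window_mm
    in_win = (heights >= lo) & (heights <= hi)
    if not np.any(in_win):
        raise DegenerateFitError("no femoral contour points in cortex window")

    pts = v[in_win]
    hs = heights[in_win]
    anterior = -(pts @ posterior_hat)                # larger = more anterior
    bins = np.floor((hs - lo) / bin_mm).astype(int)
    sel = []
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        sel.append(pts[idx[int(np.argmax(anterior[idx]))]])
    sel = np.asarray(sel)
    if len(sel) < 2:
        raise DegenerateFitError(
            f"only {len(sel)} scanline band(s) in cortex window; need >= 2")

    centroid = sel.mean(axis=0)
    _, _, vt = np.linalg.svd(sel - centroid, full_matrices=False)
    d = vt[0]
    if float(np.dot(d, distal_hat)) < 0:
        d = -d
    return DirectedLine(Point2.from_array(centroid), (float(d[0]), float(d[1])))


def femoral_sagittal_sizing(scene: KneeScene,
                            cortical_line: DirectedLine) -> tuple[float, Point2]:
    """Femoral AP length: the longest perpendicular distance from the
    anterior cortical line to the distal femoral contour, over points
    posterior to the line.  Returns ``(ap_length, most_posterior_point)``.
    """
    femur = scene.contour("femur")
    posterior_hat = _posterior_unit(scene)
    n = cortical_line.normal
    if float(np.dot(n, posterior_hat)) < 0:
        n = -n                                        # n points posteriorly
    d = (femur.vertices - cortical_line.origin.array) @ n
    idx = int(np.argmax(d))
    if d[idx] <= 0:
        raise DegenerateFitError("no femoral contour point posterior to cortex")
    return float(d[idx]), Point2.from_array(femur.vertices[idx])


def tibial_sagittal_sizing(scene: KneeScene, axis: DirectedLine,
                           slope_deg: float = 3.0, offset_mm: float = 10.0):
    """Place the sloped tibial cut and measure its AP width.

    Starting from the perpendicular to the anatomical axis ``offset_mm``
    distal to the most proximal plateau point, the line is rotated by
    ``slope_deg`` about its crossing with the axis so the posterior end
    drops (posterior slope).  Returns ``(resection, (anterior, posterior)
    inserts, ap_width, pts_deg)``.
    """
    tibia = scene.contour("tibia")
    posterior_hat = _posterior_unit(scene)
    distal_hat = axis.dir_array

    offs = project_offsets(tibia.vertices, axis)
    station = float(np.min(offs)) + offset_mm
    level = perpendicular_line_at(axis, station)
    pivot = level.point_at(0.0)                       # on the axis by construction

    cand = [rotate_line_about(level, pivot, sgn * slope_deg)
            for sgn in (+1.0, -1.0)]

    def posterior_drop(line: DirectedLine) -> float:
        r = line.dir_array
        if float(np.dot(r, posterior_hat)) < 0:
            r = -r                                    # r points posteriorly
        return float(np.dot(r, distal_hat))           # >0: posterior end lower

    resection = max(cand, key=posterior_drop)

    pts = line_polygon_intersections(resection, tibia)
    if len(pts) < 2:
        raise ResectionMissesBoneError(
            f"tibial sagittal: resection line crosses contour {len(pts)} time(s)")
    a, b = pts[0], pts[-1]
    if float(np.dot(b.array - a.array, posterior_hat)) < 0:
        a, b = b, a
    return resection, (a, b), a.distance_to(b), float(slope_deg)


def sagittal_template(scene: KneeScene, slope_deg: float = 3.0,
                      tibia_offset_mm: float = 10.0,
                      fit_window_mm: float = 60.0) -> SagittalPlan:
    """Full sagittal-plane pipeline on a calibrated lateral scene."""
    scene.validate()
    try:
        cortex = anterior_cortical_line(scene, fit_window_mm=fit_window_mm)
        ap_len, post_pt = femoral_sagittal_sizing(scene, cortex)
    except Exception as e:  # noqa: BLE001
        raise StageError("sagittal/femoral", e) from e
    try:
        axis = tibial_anatomical_axis_sagittal(scene)
        resection, inserts, ap_w, pts = tibial_sagittal_sizing(
            scene, axis, slope_deg=slope_deg, offset_mm=tibia_offset_mm)
    except Exception as e:
        raise StageError("sagittal/tibial", e) from e
    return SagittalPlan(anterior_cortical_line=cortex, femoral_ap_length=ap_len,
                        femoral_posterior_point=post_pt,
                        tibial_anatomical_axis=axis, tibial_resection=resection,
                        tibial_ap_width=ap_w, tibial_insert_points=inserts,
                        pts_deg=pts)
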