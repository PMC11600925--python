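"""File formats: mask-PNG + landmarks-JSON ingestion, reports, overlays.

The raster dialect mirrors what an upstream segmentation/landmark stack
emits: one 8-bit PNG per bone (nonzero = bone) plus a JSON file with named
landmarks, the calibration marker, view and side.  The synthetic generator
writes the same dialect, so the CLI can be exercised file-to-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import draw as skdraw
from skimage import measure as skmeasure

from . import __version__
from .calibration import CalibrationMarker, PixelScene, scene_to_pixel
from .errors import EmptyMaskError, TemplatingError
from .geometry import Point2
from .scene import KneeScene, REQUIRED_CONTOURS, REQUIRED_LANDMARKS
from .sizing import TemplatingResult

logger = logging.getLogger("kneetemplate")

__all__ = ["read_scene", "write_report", "render_overlay",
           "write_scene_bundle", "read_landmarks_file"]

SIMPLIFY_TOL_PX = 0.5


def read_landmarks_file(path: str | Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    if "landmarks" not in data or "calibration" not in data:
        raise TemplatingError(
            f"{path}: landmarks JSON needs 'landmarks' and 'calibration' keys")
    return data


def _largest_contour(mask: np.ndarray, name: str) -> np.ndarray:
    """Largest external boundary of a binary mask as (n, 2) pixel (x, y)."""
    if not np.any(mask):
        raise EmptyMaskError(f"mask {name!r} has no foreground pixels")
    padded = np.pad((mask > 0).astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise EmptyMaskError(f"mask {name!r} yielded no boundary")

    def ring_area(c: np.ndarray) -> float:
        y, x = c[:, 0], c[:, 1]
        return abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    if len(contours) > 1:
        logger.warning("mask %r has %d boundary components; using largest",
                       name, len(contours))
    best = max(contours, key=ring_area)
    xy = best[:, ::-1] - 1.0        # unpad; (row, col) -> (x, y)
    poly = ShapelyPolygon(xy).simplify(SIMPLIFY_TOL_PX, preserve_topology=True)
    coords = np.asarray(poly.exterior.coords)[:-1]
    if len(coords) < 3:
        raise EmptyMaskError(f"mask {name!r} boundary degenerate after simplify")
    return coords


def read_scene(mask_files: dict[str, str | Path],
               landmarks_file: str | Path,
               view: str | None = None) -> PixelScene:
    """Ingest one view's mask PNGs and landmarks JSON (pixel frame, y down).

    Each mask is reduced to its largest external boundary polygon
    (marching-squares at the 0.5 level, simplified to 0.5 px); landmark
    names are validated against the view's requirements.
    """
    data = read_landmarks_file(landmarks_file)
    view = view or data.get("view")
    if view not in ("AP", "LAT"):
        raise TemplatingError(f"view must be 'AP' or 'LAT', got {view!r}")
    side = data.get("side", "right")

    contours: dict[str, np.ndarray] = {}
    height = 0
    for name, path in mask_files.items():
        arr = np.asarray(Image.open(path).convert("L"))
        height = max(height, arr.shape[0])
        contours[name] = _largest_contour(arr, name)

    landmarks = {name: Point2(float(xy[0]), float(xy[1]))
                 for name, xy in data["landmarks"].items()}
    for required in REQUIRED_LANDMARKS[view]:
        if required not in landmarks:
            from .errors import MissingLandmarkError
            raise MissingLandmarkError(required, view)
    for required in REQUIRED_CONTOURS[view]:
        if required not in contours:
            from .errors import MissingContourError
            raise MissingContourError(
                f"missing required mask {required!r} for view {view}")

    cal = data["calibration"]
    marker = CalibrationMarker(
        Point2(float(cal["p1"][0]), float(cal["p1"][1])),
        Point2(float(cal["p2"][0]), float(cal["p2"][1])),
        float(cal["mm"]))
    return PixelScene(view=view, side=side, contours=contours,
                      landmarks=landmarks, marker=marker,
                      image_height_px=height)


def write_scene_bundle(scene: KneeScene, out_dir: str | Path,
                       margin_px: int = 20) -> dict[str, Path]:
    """Write a calibrated scene in the raster dialect :func:`read_scene` reads.

    The canvas height is derived from the scene's extent at its calibration
    scale; the marker is synthesized so calibration round-trips exactly.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    s = scene.calibration.mm_per_pixel
    all_y = np.concatenate([c.vertices[:, 1] for c in scene.contours.values()])
    all_x = np.concatenate([c.vertices[:, 0] for c in scene.contours.values()])
    height = int(math.ceil(all_y.max() / s)) + margin_px
    width = int(math.ceil(all_x.max() / s)) + margin_px
    if all_y.min() < 0 or all_x.min() < 0:
        raise TemplatingError("scene extends below the raster origin; "
                              "translate it into the positive quadrant first")

    px = scene_to_pixel(scene, scene.calibration, height)
    paths: dict[str, Path] = {}
    for name, v in px.contours.items():
        rr, cc = skdraw.polygon(v[:, 1], v[:, 0], shape=(height, width))
        mask = np.zeros((height, width), dtype=np.uint8)
        mask[rr, cc] = 255
        p = out_dir / f"{name}.png"
        Image.fromarray(mask).save(p)
        paths[name] = p

    data = {
        "view": scene.view,
        "side": scene.side,
        "landmarks": {k: [p.x, p.y] for k, p in px.landmarks.items()},
        "calibration": {"p1": [px.marker.p1.x, px.marker.p1.y],
                        "p2": [px.marker.p2.x, px.marker.p2.y],
                        "mm": px.marker.known_separation_mm},
    }
    lm_path = out_dir / "landmarks.json"
    with open(lm_path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
    paths["landmarks"] = lm_path
    return paths


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _point_pair(pair) -> list[list[float]]:
    return [[round(p.x, 6), round(p.y, 6)] for p in pair]


def result_to_dict(result: TemplatingResult,
                   input_files: dict[str, str | Path] | None = None) -> dict:
    cor, sag = result.coronal_plan, result.sagittal_plan
    doc = {
        "tool": {"name": "kneetemplate", "version": __version__},
        "sizes": {
            comp.component: {
                "coronal": comp.coronal_size,
                "sagittal": comp.sagittal_size,
                "merged": comp.merged_size,
                "flags": sorted(comp.flags),
            }
            for comp in (result.femoral, result.tibial)
        },
        "widths_mm": {
            "femoral_ml": round(cor.femoral_ml_width, 4),
            "tibial_ml": round(cor.tibial_ml_width, 4),
            "femoral_ap": round(sag.femoral_ap_length, 4),
            "tibial_ap": round(sag.tibial_ap_width, 4),
        },
        "angles_deg": {
            "hka": round(cor.hka_deg, 3),
            "mpta": round(cor.mpta_deg, 3),
            "pts": round(sag.pts_deg, 3),
        },
        "coronal": {
            "mpta_adjusted": cor.mpta_adjusted,
            "lesser_side": cor.lesser_side,
            "lesser_side_depth_mm": round(cor.lesser_side_depth_mm, 4),
            "femoral_insert_points": _point_pair(cor.femoral_insert_points),
            "tibial_insert_points": _point_pair(cor.tibial_insert_points),
        },
        "sagittal": {
            "tibial_insert_points": _point_pair(sag.tibial_insert_points),
            "femoral_posterior_point": [
                round(sag.femoral_posterior_point.x, 6),
                round(sag.femoral_posterior_point.y, 6)],
        },
    }
    if input_files:
        doc["inputs"] = {k: {"path": str(Path(p).name),
                             "sha256": _file_sha256(p)}
                         for k, p in sorted(input_files.items())}
    return doc


def write_report(result: TemplatingResult, path: str | Path,
                 input_files: dict[str, str | Path] | None = None) -> None:
    """Serialize a templating result as deterministic, stable-key JSON."""
    doc = result_to_dict(result, input_files)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def render_overlay(scene: KneeScene, result: TemplatingResult,
                   path: str | Path, charts=None) -> None:
    """Draw contours, axes, resection lines, insert points and a
    rectangle-proxy implant of the merged size onto a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .sizing import default_chart
    charts = charts if charts is not None else default_chart()

    fig, ax = plt.subplots(figsize=(6, 9))
    for name, c in scene.contours.items():
        v = np.vstack([c.vertices, c.vertices[:1]])
        ax.plot(v[:, 0], v[:, 1], "-", lw=1.0, label=name)
    for name, p in scene.landmarks.items():
        ax.plot(p.x, p.y, "k+", ms=6)

    cor, sag = result.coronal_plan, result.sagittal_plan

    def draw_line(line, span, style, label=None):
        ts = np.array([-span, span])
        pts = np.array([[line.origin.x + t * line.direction[0],
                         line.origin.y + t * line.direction[1]] for t in ts])
        ax.plot(pts[:, 0], pts[:, 1], style, lw=1.2, label=label)

    def draw_implant(line, mid, extent_mm, thickness_mm=8.0):
        d = np.array(line.direction)
        n = np.array([-d[1], d[0]])
        m = np.array([mid.x, mid.y])
        corners = np.array([m - d * extent_mm / 2, m + d * extent_mm / 2,
                            m + d * extent_mm / 2 - n * thickness_mm,
                            m - d * extent_mm / 2 - n * thickness_mm,
                            m - d * extent_mm / 2])
        ax.plot(corners[:, 0], corners[:, 1], "m-", lw=1.5)

    if scene.view == "AP":
        draw_line(cor.fma, 500, "b--", "FMA")
        draw_line(cor.tma, 400, "g--", "TMA")
        draw_line(cor.femoral_resection, 60, "r-")
        draw_line(cor.tibial_resection, 60, "r-")
        for p in (*cor.femoral_insert_points, *cor.tibial_insert_points):
            ax.plot(p.x, p.y, "ro", ms=4)
        fm = result.femoral.merged_size
        tm = result.tibial.merged_size
        f_mid = Point2(*(np.mean([[p.x, p.y] for p in cor.femoral_insert_points],
                                 axis=0)))
        t_mid = Point2(*(np.mean([[p.x, p.y] for p in cor.tibial_insert_points],
                                 axis=0)))
        draw_implant(cor.femoral_resection, f_mid,
                     charts["femoral"].entry(fm).ml_mm)
        draw_implant(cor.tibial_resection, t_mid,
                     charts["tibial"].entry(tm).ml_mm)
    else:
        draw_line(sag.anterior_cortical_line, 120, "b--", "cortex")
        draw_line(sag.tibial_anatomical_axis, 150, "g--", "axis")
        draw_line(sag.tibial_resection, 50, "r-")
        for p in sag.tibial_insert_points:
            ax.plot(p.x, p.y, "ro", ms=4)
        ax.plot(sag.femoral_posterior_point.x, sag.femoral_posterior_point.y,
                "ro", ms=4)
        tm = result.tibial.merged_size
        t_mid = Point2(*(np.mean([[p.x, p.y] for p in sag.tibial_insert_points],
                                 axis=0)))
        draw_implant(sag.tibial_resection, t_mid,
                     charts["tibial"].entry(tm).ap_mm)

    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=7)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.savefig(path, dpi=100)
    plt.close(fig)
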