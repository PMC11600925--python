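"""Seeded parametric knee generator with analytic ground truth.

Scenes are piecewise line/arc silhouettes — not statistical shape models —
chosen so that every quantity the templating pipeline measures has a
closed form:

* AP femur: a shaft flaring into two circular condylar arcs of radius
  ``R`` whose lowest points sit level, so the mediolateral chord 9 mm
  above the distal condyle is ``2 d + 2 sqrt(R^2 - (R - 9)^2)`` for condyle
  centers at ``x = +-d``.
* AP tibia: a plateau whose sides flare outward at a fixed slope, so the
  chord 10 mm below the highest (lateral) plateau corner is linear in the
  flare and in the medial attrition ``a`` (the medial corner sits ``a`` mm
  lower, emulating wear in varus osteoarthritis).
* LAT femur: a straight anterior cortex plus a circular posterior condyle,
  so the anterior-cortex-to-condyle AP length is exactly the circle's
  posterior reach.
* LAT tibia: a rectangular upper segment, so the 3-degree sloped chord is
  ``depth / cos(slope)``.

A single truth object drives both views; the hip-knee-ankle angle is
imposed by rigidly rotating the tibia (with its landmarks) about the
plateau midpoint, and the whole scene receives a small random rigid motion
so nothing is axis-aligned by accident.  Contour noise perturbs vertices
uniformly; landmark jitter perturbs landmarks independently.  Everything
is deterministic given the truth's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import Calibration
from .errors import GenerationError
from .geometry import ContourPolygon, Point2
from .scene import KneeScene
from .sizing import ImplantSizeChart, default_chart

__all__ = ["SyntheticKneeTruth", "generate_truth", "generate_ap_scene",
           "generate_lat_scene", "generate_knee", "generate_cohort"]

CONDYLE_RADIUS_AP = 23.0       # mm, coronal condylar arc radius
CONDYLE_RADIUS_LAT = 21.0      # mm, sagittal posterior condyle radius
TIBIA_FLARE = 0.6              # mm of half-width per mm of depth below plateau
TIBIA_FLARE_DEPTH = 18.0       # mm, extent of the metaphyseal flare
FEMUR_STATION_MM = 9.0         # distal femoral resection thickness
TIBIA_STATION_MM = 10.0        # tibial resection offset
DEFAULT_SLOPE_DEG = 3.0
JOINT_GAP_AP = 7.0             # mm, radiographic joint space on AP
JOINT_GAP_LAT = 6.0


@dataclass(frozen=True)
class SyntheticKneeTruth:
    """Generator parameters plus the analytic ground truth they imply.

    The recorded widths are the analytic cross-sections at the pipeline's
    measurement stations: 9 mm (femur coronal), 10 mm (tibia coronal), the
    anterior cortical line (femur sagittal) and the 3-degree sloped chord
    (tibia sagittal).
    """

    seed: int
    side: str
    hka_deg: float                 # varus positive
    medial_attrition_mm: float
    femoral_ml_mm: float
    tibial_ml_mm: float
    femoral_ap_mm: float
    tibial_ap_mm: float
    true_sizes: dict = field(default_factory=dict)   # component -> size label
    mm_per_pixel: float = 0.15
    noise_mm: float = 0.0
    landmark_jitter_mm: float = 0.0

    def __post_init__(self):
        for name in ("femoral_ml_mm", "tibial_ml_mm",
                     "femoral_ap_mm", "tibial_ap_mm"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if self.medial_attrition_mm < 0:
            raise GenerationError("attrition cannot be negative")
        if self.side not in ("left", "right"):
            raise GenerationError(f"unknown side {self.side!r}")


# ---------------------------------------------------------------------------
# truth sampling

_SIZE_P = np.array([0.05, 0.17, 0.27, 0.25, 0.15, 0.07, 0.03, 0.01])
_BIN_LO, _BIN_HI = 0.15, 0.85   # width position within its size bin


def _chart_width(chart: ImplantSizeChart, dimension: str, size: int,
                 u: float) -> float:
    """A bone width that belongs to ``size``'s bin: chart value plus a
    fraction ``u`` of the (constant) inter-size step."""
    dims = chart.dims(dimension)
    sizes = [e.size for e in chart.entries]
    i = sizes.index(size)
    if len(dims) == 1:
        gap = 2.0
    elif i + 1 < len(dims):
        gap = dims[i + 1] - dims[i]
    else:
        gap = dims[i] - dims[i - 1]
    return dims[i] + u * gap


def generate_truth(seed: int,
                   charts: dict[str, ImplantSizeChart] | None = None,
                   noise_mm: float = 0.3,
                   landmark_jitter_mm: float = 0.5,
                   side: str | None = None,
                   hka_deg: float | None = None,
                   medial_attrition_mm: float | None = None,
                   femoral_size: int | None = None,
                   tibial_size: int | None = None,
                   mm_per_pixel: float | None = None) -> SyntheticKneeTruth:
    """Sample one knee's parameters; any argument given overrides the draw.

    Default distributions mirror a varus-dominant osteoarthritis cohort
    (about 78% varus above 3 degrees, a small valgus minority, mid-range
    implant sizes most common) without claiming anatomical realism.
    Severe attrition is excluded, as such knees are not templated by the
    standard workflow.
    """
    charts = charts if charts is not None else default_chart()
    rng = np.random.default_rng(seed)

    if side is None:
        side = "right" if rng.random() < 0.543 else "left"
    if hka_deg is None:
        r = rng.random()
        if r < 0.777:
            hka_deg = float(rng.uniform(3.0, 12.0))
        elif r < 0.863:
            hka_deg = float(rng.uniform(-3.0, 3.0))
        else:
            hka_deg = float(rng.uniform(-8.0, -3.0))
    if medial_attrition_mm is None:
        medial_attrition_mm = float(np.clip(
            0.35 * max(hka_deg, 0.0) + rng.uniform(0.0, 2.0), 0.0, 7.5))
    if femoral_size is None:
        femoral_size = int(rng.choice(np.arange(1, 9), p=_SIZE_P))
    if tibial_size is None:
        tibial_size = int(np.clip(
            femoral_size + rng.choice([-1, 0, 0, 0, 1]), 1, 8))
    if mm_per_pixel is None:
        mm_per_pixel = float(rng.uniform(0.12, 0.20))

    u = rng.uniform(_BIN_LO, _BIN_HI, size=4)
    return SyntheticKneeTruth(
        seed=int(seed), side=side, hka_deg=float(hka_deg),
        medial_attrition_mm=float(medial_attrition_mm),
        femoral_ml_mm=_chart_width(charts["femoral"], "ml", femoral_size, u[0]),
        tibial_ml_mm=_chart_width(charts["tibial"], "ml", tibial_size, u[1]),
        femoral_ap_mm=_chart_width(charts["femoral"], "ap", femoral_size, u[2]),
        tibial_ap_mm=_chart_width(charts["tibial"], "ap", tibial_size, u[3]),
        true_sizes={"femoral": femoral_size, "tibial": tibial_size},
        mm_per_pixel=mm_per_pixel, noise_mm=float(noise_mm),
        landmark_jitter_mm=float(landmark_jitter_mm))


# ---------------------------------------------------------------------------
# silhouette building blocks


def _subdivide(points: np.ndarray, max_step: float) -> np.ndarray:
    """Insert vertices so no polyline edge exceeds ``max_step`` (open path)."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        n = max(1, int(math.ceil(np.linalg.norm(b - a) / max_step)))
        for k in range(1, n + 1):
            out.append(a + (b - a) * (k / n))
    return np.asarray(out)


def _arc(center: np.ndarray, radius: float, deg_from: float, deg_to: float,
         step_deg: float = 3.0, include: tuple[float, ...] = ()) -> np.ndarray:
    """Arc vertices from ``deg_from`` to ``deg_to`` (CCW if to > from),
    guaranteeing any angle in ``include`` appears exactly."""
    n = max(2, int(math.ceil(abs(deg_to - deg_from) / step_deg)) + 1)
    angles = np.linspace(deg_from, deg_to, n)
    keys = [a for a in include if min(deg_from, deg_to) < a < max(deg_from, deg_to)]
    angles = np.unique(np.concatenate([angles, np.asarray(keys, dtype=float)]))
    if deg_to < deg_from:
        angles = angles[::-1]
    th = np.radians(angles)
    return center + radius * np.column_stack([np.cos(th), np.sin(th)])


def _femur_ap(w_ml: float) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Distal femur silhouette in its local frame (FMA = +y, distal at 0)."""
    R = CONDYLE_RADIUS_AP
    half_chord = math.sqrt(R * R - (R - FEMUR_STATION_MM) ** 2)
    d = w_ml / 2.0 - half_chord
    if not (0.0 < d < R):
        raise GenerationError(
            f"femoral ML width {w_ml:.1f} mm incompatible with condyle radius")
    notch_deg = math.degrees(math.acos(d / R))
    outer_y = 14.0                                     # arc span above the chord
    outer_deg = math.degrees(math.asin((outer_y - R) / R))   # negative
    w_shaft = 14.0
    lc, rc = np.array([-d, R]), np.array([d, R])

    left_arc = _arc(lc, R, 180.0 - outer_deg, 360.0 - notch_deg,
                    include=(270.0,))
    right_arc = _arc(rc, R, 180.0 + notch_deg, 360.0 + outer_deg,
                     include=(270.0,))
    path = [
        _subdivide(np.array([[-w_shaft, 120.0], [-w_shaft, 55.0]]), 6.0),
        _subdivide(np.array([[-w_shaft, 55.0], left_arc[0]]), 5.0)[1:],
        left_arc[1:],
        right_arc[1:],
        _subdivide(np.array([right_arc[-1], [w_shaft, 55.0]]), 5.0)[1:],
        _subdivide(np.array([[w_shaft, 55.0], [w_shaft, 120.0]]), 6.0)[1:],
        _subdivide(np.array([[w_shaft, 120.0], [-w_shaft, 120.0]]), 6.0)[1:-1],
    ]
    vertices = np.vstack(path)
    landmarks = {"femoral_head_center": np.array([0.0, 420.0]),
                 "trochlear_groove": np.array([0.0, 8.0])}
    return vertices, landmarks


def _tibia_ap(w_ml: float, attrition: float) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Proximal tibia silhouette, local frame: TMA = y axis, medial = +x.

    The plateau's lateral corner sits at height 0, the medial corner
    ``attrition`` mm lower; both sides flare outward at ``TIBIA_FLARE`` so
    the chord 10 mm down has width ``w_top + f*10 + f*(10 - attrition)``.
    """
    f, df = TIBIA_FLARE, TIBIA_FLARE_DEPTH
    w_top = w_ml - f * (2.0 * TIBIA_STATION_MM - attrition)
    if w_top <= 10.0:
        raise GenerationError("tibial ML width too small for plateau model")
    a = attrition
    L = np.array([-w_top / 2.0, 0.0])
    M = np.array([w_top / 2.0, -a])
    med_flare = np.array([w_top / 2.0 + f * (df - a), -df])
    lat_flare = np.array([-w_top / 2.0 - f * df, -df])
    path = [
        _subdivide(np.vstack([L, M]), 3.0),
        _subdivide(np.vstack([M, med_flare]), 3.0)[1:],
        _subdivide(np.array([med_flare, [11.0, -60.0], [11.0, -320.0],
                             [22.0, -332.0], [0.0, -340.0], [-22.0, -332.0],
                             [-11.0, -320.0], [-11.0, -60.0], lat_flare]),
                   6.0)[1:],
        _subdivide(np.vstack([lat_flare, L]), 3.0)[1:-1],
    ]
    vertices = np.vstack(path)
    landmarks = {"tibial_plateau_lateral": L.copy(),
                 "tibial_plateau_medial": M.copy(),
                 "talar_dome_center": np.array([0.0, -340.0])}
    return vertices, landmarks


def _femur_lat(ap_len: float) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Lateral femur: straight anterior cortex at x = 0, posterior condyle
    circle reaching x = ``ap_len`` (posterior = +x)."""
    R = CONDYLE_RADIUS_LAT
    cx = ap_len - R
    if cx <= R * 0.3:
        raise GenerationError(
            f"femoral AP length {ap_len:.1f} mm incompatible with condyle radius")
    center = np.array([cx, R])
    arc = _arc(center, R, 180.0, 450.0, include=(270.0, 360.0))
    path = [
        _subdivide(np.array([[0.0, 130.0], [0.0, 18.0]]), 1.0),
        _subdivide(np.array([[0.0, 18.0], arc[0]]), 3.0)[1:],
        arc[1:],
        _subdivide(np.array([arc[-1], [26.0, 130.0]]), 5.0)[1:],
        _subdivide(np.array([[26.0, 130.0], [0.0, 130.0]]), 6.0)[1:-1],
    ]
    return np.vstack(path), {}


def _tibia_lat(ap_chord: float,
               slope_deg: float = DEFAULT_SLOPE_DEG) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Lateral tibia: rectangular upper segment of depth ``D`` such that the
    ``slope_deg`` chord equals ``ap_chord`` = D / cos(slope)."""
    D = ap_chord * math.cos(math.radians(slope_deg))
    h = D / 2.0
    top = -JOINT_GAP_LAT     # plateau level; femur's distal condyle sits at 0
    path = [
        _subdivide(np.array([[-h, top], [h, top]]), 2.5),
        _subdivide(np.array([[h, top], [h, top - 26.0]]), 3.0)[1:],
        _subdivide(np.array([[h, top - 26.0], [10.0, top - 54.0],
                             [10.0, top - 114.0], [-10.0, top - 114.0],
                             [-10.0, top - 54.0], [-h, top - 26.0]]), 5.0)[1:],
        _subdivide(np.array([[-h, top - 26.0], [-h, top]]), 3.0)[1:-1],
    ]
    landmarks = {"plateau_anterior": np.array([-h, top]),
                 "plateau_posterior": np.array([h, top]),
                 "tibial_shaft_proximal": np.array([0.0, top - 39.0]),
                 "tibial_shaft_distal": np.array([0.0, top - 104.0])}
    return np.vstack(path), landmarks


# ---------------------------------------------------------------------------
# scene assembly


def _rot(deg: float) -> np.ndarray:
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s], [s, c]])


def _apply(points: np.ndarray, matrix: np.ndarray, shift: np.ndarray,
           pivot: np.ndarray | None = None) -> np.ndarray:
    p = np.zeros(2) if pivot is None else np.asarray(pivot)
    return (points - p) @ matrix.T + p + shift


def _decimate(vertices: np.ndarray, min_spacing: float) -> np.ndarray:
    """Drop vertices closer than ``min_spacing`` to the previously kept one,
    so independent vertex jitter cannot fold the boundary."""
    keep = [0]
    for i in range(1, len(vertices)):
        if np.linalg.norm(vertices[i] - vertices[keep[-1]]) >= min_spacing:
            keep.append(i)
    if len(keep) > 3 and np.linalg.norm(vertices[keep[-1]] - vertices[0]) < min_spacing:
        keep.pop()
    return vertices[keep]


def _noisy_polygon(vertices: np.ndarray, noise: float,
                   rng: np.random.Generator, what: str) -> ContourPolygon:
    if noise <= 0:
        return ContourPolygon(vertices)
    vertices = _decimate(vertices, 2.8 * noise)
    for _ in range(12):
        jit = rng.uniform(-noise, noise, size=vertices.shape)
        poly = ContourPolygon(vertices + jit)
        if poly.is_simple():
            return poly
    raise GenerationError(
        f"{what}: contour noise {noise} mm kept producing self-intersections")


def _jitter_landmarks(landmarks: dict[str, np.ndarray], jitter: float,
                      rng: np.random.Generator) -> dict[str, Point2]:
    out = {}
    for name, p in landmarks.items():
        q = p + (rng.uniform(-jitter, jitter, size=2) if jitter > 0 else 0.0)
        out[name] = Point2(float(q[0]), float(q[1]))
    return out


def generate_ap_scene(truth: SyntheticKneeTruth) -> tuple[KneeScene, dict]:
    """Full-leg AP scene plus its analytic oracle.

    The femur is placed with its mechanical axis vertical; the tibia is
    rotated about the plateau midpoint by the hip-knee-ankle angle (varus
    positive tips the ankle medially).  Left knees are mirrored.
    """
    rng = np.random.default_rng([truth.seed, 0])

    femur_v, femur_lm = _femur_ap(truth.femoral_ml_mm)
    tibia_v, tibia_lm = _tibia_ap(truth.tibial_ml_mm, truth.medial_attrition_mm)

    # drop the tibia below the joint space, then impose the deformity
    tibia_v = tibia_v + np.array([0.0, -JOINT_GAP_AP])
    tibia_lm = {k: v + np.array([0.0, -JOINT_GAP_AP]) for k, v in tibia_lm.items()}
    pivot = (tibia_lm["tibial_plateau_medial"]
             + tibia_lm["tibial_plateau_lateral"]) / 2.0
    Rk = _rot(truth.hka_deg)            # +hka tips the distal tibia medially (+x)
    tibia_v = _apply(tibia_v, Rk, np.zeros(2), pivot)
    tibia_lm = {k: _apply(v[None, :], Rk, np.zeros(2), pivot)[0]
                for k, v in tibia_lm.items()}

    contours = {"femur": femur_v, "tibia": tibia_v}
    landmarks = {**femur_lm, **tibia_lm}

    if truth.side == "left":
        for k in contours:
            contours[k] = contours[k] * np.array([-1.0, 1.0])
        landmarks = {k: v * np.array([-1.0, 1.0]) for k, v in landmarks.items()}

    # small global rigid motion so nothing stays axis-aligned
    Rg = _rot(float(rng.uniform(-2.0, 2.0)))
    shift = np.array([120.0, 380.0]) + rng.uniform(-10.0, 10.0, size=2)
    for k in contours:
        contours[k] = _apply(contours[k], Rg, shift)
    landmarks = {k: _apply(v[None, :], Rg, shift)[0] for k, v in landmarks.items()}

    scene = KneeScene(
        view="AP", side=truth.side,
        contours={k: _noisy_polygon(v, truth.noise_mm, rng, f"AP {k}")
                  for k, v in contours.items()},
        landmarks=_jitter_landmarks(landmarks, truth.landmark_jitter_mm, rng),
        calibration=Calibration(truth.mm_per_pixel),
        meta={"seed": truth.seed, "generator": "synthetic"})
    oracle = {
        "femoral_ml_mm": truth.femoral_ml_mm,
        "tibial_ml_mm": truth.tibial_ml_mm,
        "hka_deg": truth.hka_deg,
        "lesser_side_depth_mm": TIBIA_STATION_MM - truth.medial_attrition_mm,
        "expects_mpta_adjustment":
            TIBIA_STATION_MM - truth.medial_attrition_mm < 2.0,
    }
    return scene.validate(), oracle


def generate_lat_scene(truth: SyntheticKneeTruth) -> tuple[KneeScene, dict]:
    """Lateral knee scene plus its analytic oracle (posterior = +x before
    mirroring; left knees are mirrored)."""
    rng = np.random.default_rng([truth.seed, 1])

    femur_v, _ = _femur_lat(truth.femoral_ap_mm)
    tibia_v, tibia_lm = _tibia_lat(truth.tibial_ap_mm)
    patella_v = _subdivide(np.array([[-16.0, 25.0], [-8.0, 25.0], [-8.0, 70.0],
                                     [-16.0, 70.0], [-16.0, 25.0]]), 4.0)[:-1]
    fibula_v = _subdivide(np.array([[16.0, -100.0], [24.0, -100.0],
                                    [24.0, -40.0], [16.0, -40.0],
                                    [16.0, -100.0]]), 5.0)[:-1]

    contours = {"femur": femur_v, "tibia": tibia_v,
                "patella": patella_v, "fibula": fibula_v}
    landmarks = dict(tibia_lm)

    if truth.side == "left":
        for k in contours:
            contours[k] = contours[k] * np.array([-1.0, 1.0])
        landmarks = {k: v * np.array([-1.0, 1.0]) for k, v in landmarks.items()}

    Rg = _rot(float(rng.uniform(-2.0, 2.0)))
    shift = np.array([90.0, 160.0]) + rng.uniform(-10.0, 10.0, size=2)
    for k in contours:
        contours[k] = _apply(contours[k], Rg, shift)
    landmarks = {k: _apply(v[None, :], Rg, shift)[0] for k, v in landmarks.items()}

    scene = KneeScene(
        view="LAT", side=truth.side,
        contours={k: _noisy_polygon(v, truth.noise_mm, rng, f"LAT {k}")
                  for k, v in contours.items()},
        landmarks=_jitter_landmarks(landmarks, truth.landmark_jitter_mm, rng),
        calibration=Calibration(truth.mm_per_pixel),
        meta={"seed": truth.seed, "generator": "synthetic"})
    oracle = {"femoral_ap_mm": truth.femoral_ap_mm,
              "tibial_ap_mm": truth.tibial_ap_mm,
              "slope_deg": DEFAULT_SLOPE_DEG}
    return scene.validate(), oracle


def generate_knee(truth: SyntheticKneeTruth) -> tuple[KneeScene, KneeScene]:
    """Both views of one knee (oracles dropped)."""
    ap, _ = generate_ap_scene(truth)
    lat, _ = generate_lat_scene(truth)
    return ap, lat


def generate_cohort(n: int, seed: int,
                    charts: dict[str, ImplantSizeChart] | None = None,
                    noise_mm: float = 0.3,
                    landmark_jitter_mm: float = 0.5,
                    **overrides) -> list[tuple[SyntheticKneeTruth, KneeScene, KneeScene]]:
    """``n`` independent seeded knees: (truth, AP scene, LAT scene) triples.

    Keyword overrides are forwarded to :func:`generate_truth` and hold the
    given parameter fixed across the cohort.
    """
    if n < 1:
        raise GenerationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        sub = int(rng.integers(0, 2**31 - 1))
        truth = generate_truth(sub, charts=charts, noise_mm=noise_mm,
                               landmark_jitter_mm=landmark_jitter_mm,
                               **overrides)
        ap, _ = generate_ap_scene(truth)
        lat, _ = generate_lat_scene(truth)
        out.append((truth, ap, lat))
    return out
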