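import numpy as np
import pytest

from kneetemplate.calibration import Calibration
from kneetemplate.geometry import ContourPolygon, Point2
from kneetemplate.scene import KneeScene
from kneetemplate.sizing import default_chart
from kneetemplate.synthetic import (generate_ap_scene, generate_lat_scene,
                                    generate_truth)


@pytest.fixture(scope="session")
def charts():
    return default_chart()


@pytest.fixture
def noiseless_truth():
    """Factory: a fully deterministic knee with no noise or jitter."""

    def make(seed=0, **overrides):
        overrides.setdefault("noise_mm", 0.0)
        overrides.setdefault("landmark_jitter_mm", 0.0)
        return generate_truth(seed, **overrides)

    return make


@pytest.fixture
def noiseless_knee(noiseless_truth):
    """Factory: (truth, ap_scene, lat_scene) with no noise."""

    def make(seed=0, **overrides):
        truth = noiseless_truth(seed, **overrides)
        ap, _ = generate_ap_scene(truth)
        lat, _ = generate_lat_scene(truth)
        return truth, ap, lat

    return make


def rectangle_polygon(cx, cy, width, height, step=2.0):
    """Axis-aligned rectangle contour subdivided to ~step mm edges."""
    from kneetemplate.synthetic import _subdivide

    x0, x1 = cx - width / 2, cx + width / 2
    y0, y1 = cy - height / 2, cy + height / 2
    ring = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]])
    return ContourPolygon(_subdivide(ring, step)[:-1])


@pytest.fixture
def rect_ap_scene():
    """AP scene with rectangular femur/tibia phantoms and exact landmarks."""

    def make(femur_w=60.0, tibia_w=64.0):
        femur = rectangle_polygon(0.0, 60.0, femur_w, 120.0)
        tibia = rectangle_polygon(0.0, -87.0, tibia_w, 160.0)
        landmarks = {
            "femoral_head_center": Point2(0.0, 420.0),
            "trochlear_groove": Point2(0.0, 10.0),
            "tibial_plateau_medial": Point2(tibia_w / 2, -7.0),
            "tibial_plateau_lateral": Point2(-tibia_w / 2, -7.0),
            "talar_dome_center": Point2(0.0, -350.0),
        }
        return KneeScene(view="AP", side="right",
                         contours={"femur": femur, "tibia": tibia},
                         landmarks=landmarks,
                         calibration=Calibration(0.15))

    return make


@pytest.fixture
def rect_lat_scene():
    """Lateral scene with a rectangular tibia (sloped-chord closed form)."""

    def make(femur_ap=62.0, tibia_ap=48.0):
        # femur: rectangle whose anterior face is a straight cortex at x=0
        femur = rectangle_polygon(femur_ap / 2, 60.0, femur_ap, 120.0, step=1.0)
        tibia = rectangle_polygon(femur_ap / 2, -86.0, tibia_ap, 160.0)
        patella = rectangle_polygon(-10.0, 50.0, 8.0, 40.0)
        fibula = rectangle_polygon(femur_ap / 2 + tibia_ap / 2 + 6, -80.0,
                                   8.0, 60.0)
        cx = femur_ap / 2
        landmarks = {
            "plateau_anterior": Point2(cx - tibia_ap / 2, -6.0),
            "plateau_posterior": Point2(cx + tibia_ap / 2, -6.0),
            "tibial_shaft_proximal": Point2(cx, -40.0),
            "tibial_shaft_distal": Point2(cx, -140.0),
        }
        return KneeScene(view="LAT", side="right",
                         contours={"femur": femur, "tibia": tibia,
                                   "patella": patella, "fibula": fibula},
                         landmarks=landmarks,
                         calibration=Calibration(0.15))

    return make
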