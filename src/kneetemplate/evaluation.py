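"""Agreement statistics and postoperative registration for validation.

Size predictions are compared with the implanted sizes using the standard
templating taxonomy: *exact* (same size), *accurate* (within one size,
inclusive of exact), and *inaccurate* predictions split into over- and
underestimates.  Rater-vs-truth reliability uses Cohen's kappa with
quadratic weights, the conventional statistic for ordinal size ladders.

Positioning accuracy maps manually marked postoperative implant points
into the preoperative frame with a similarity transform — scale and
translation from corresponding point pairs, rotation refined by maximizing
segmentation-mask overlap — and measures distances between predicted and
achieved implant reference points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import (TemplatingError, UndefinedKappaError,
                     UnderdeterminedTransformError)
from .geometry import DirectedLine, Point2, angle_between_deg

__all__ = ["SizeAgreementRecord", "SimilarityTransform2D",
           "classify_prediction", "agreement_summary",
           "quadratic_weighted_kappa", "kappa_reliability_band",
           "fit_similarity_transform", "positioning_error"]


@dataclass(frozen=True)
class SizeAgreementRecord:
    predicted: int
    actual: int

    @property
    def category(self) -> str:
        return classify_prediction(self.predicted, self.actual)


def classify_prediction(predicted: int, actual: int) -> str:
    """Exact / accurate / overestimate / underestimate per size difference.

    ``accurate`` here means strictly within-one (the one-size margin);
    exact cases are counted inside the accurate total by
    :func:`agreement_summary`, matching the inclusive taxonomy.
    """
    delta = int(predicted) - int(actual)
    if delta == 0:
        return "exact"
    if abs(delta) == 1:
        return "accurate"
    return "overestimate" if delta > 0 else "underestimate"


def agreement_summary(records: Sequence[SizeAgreementRecord | tuple[int, int]]) -> dict:
    """Counts and percentages of the taxonomy over a record set.

    ``accurate`` is inclusive (exact or within one size); percentages are
    reported to one decimal.
    """
    if len(records) == 0:
        raise TemplatingError("agreement summary needs at least one record")
    cats = []
    for r in records:
        if isinstance(r, SizeAgreementRecord):
            cats.append(r.category)
        else:
            cats.append(classify_prediction(r[0], r[1]))
    n = len(cats)
    exact = cats.count("exact")
    within_one = cats.count("accurate")
    over = cats.count("overestimate")
    under = cats.count("underestimate")
    accurate = exact + within_one
    pct = lambda k: round(100.0 * k / n, 1)  # noqa: E731
    return {
        "n": n,
        "exact": exact, "exact_pct": pct(exact),
        "accurate": accurate, "accurate_pct": pct(accurate),
        "overestimate": over, "overestimate_pct": pct(over),
        "underestimate": under, "underestimate_pct": pct(under),
    }


def quadratic_weighted_kappa(predicted: Sequence[int], actual: Sequence[int],
                             categories: Sequence[int] | None = None) -> float:
    """Cohen's kappa with quadratic weights over an ordered size ladder.

    ``kappa = 1 - sum(w * O) / sum(w * E)`` with ``w_ij = (i - j)^2 /
    (k - 1)^2``, observed proportions ``O`` and chance expectation ``E``
    from the marginal products.
    """
    predicted = list(predicted)
    actual = list(actual)
    if len(predicted) != len(actual):
        raise TemplatingError("predicted/actual lists differ in length")
    if len(predicted) < 2:
        raise TemplatingError("kappa needs at least two paired ratings")
    if categories is None:
        categories = sorted(set(predicted) | set(actual))
    cats = list(categories)
    k = len(cats)
    if k < 2:
        raise UndefinedKappaError("all mass in a single category")
    index = {c: i for i, c in enumerate(cats)}
    try:
        pi = [index[p] for p in predicted]
        ai = [index[a] for a in actual]
    except KeyError as e:
        raise TemplatingError(f"label {e.args[0]!r} not in categories") from None

    n = len(pi)
    obs = np.zeros((k, k))
    np.add.at(obs, (pi, ai), 1.0)
    obs /= n
    marg_p = obs.sum(axis=1)
    marg_a = obs.sum(axis=0)
    expected = np.outer(marg_p, marg_a)
    i = np.arange(k)
    w = (i[:, None] - i[None, :]) ** 2 / (k - 1) ** 2
    denom = float(np.sum(w * expected))
    if denom < 1e-15:
        raise UndefinedKappaError("zero expected disagreement")
    return float(1.0 - np.sum(w * obs) / denom)


def kappa_reliability_band(kappa: float) -> str:
    """Conventional qualitative band for a kappa value."""
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


# ---------------------------------------------------------------------------
# postoperative registration


@dataclass(frozen=True)
class SimilarityTransform2D:
    """Maps postoperative coordinates into the preoperative frame:
    ``q = scale * R(rotation) @ p + translation``."""

    scale: float
    rotation_deg: float
    translation: tuple[float, float]

    def __post_init__(self):
        if self.scale <= 0:
            raise TemplatingError("similarity scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray | Point2):
        if isinstance(points, Point2):
            q = self.matrix @ points.array + np.asarray(self.translation)
            return Point2(float(q[0]), float(q[1]))
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.matrix.T + np.asarray(self.translation)


def _fit_scale_translation(pre: np.ndarray, post: np.ndarray,
                           rotation_deg: float) -> tuple[float, np.ndarray]:
    """Least-squares scale and translation for a fixed rotation."""
    th = math.radians(rotation_deg)
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    rp = post @ R.T
    pre_c = pre - pre.mean(axis=0)
    rp_c = rp - rp.mean(axis=0)
    denom = float(np.sum(rp_c * rp_c))
    if denom < 1e-12:
        raise UnderdeterminedTransformError("corresponding points coincide")
    s = float(np.sum(pre_c * rp_c)) / denom
    t = pre.mean(axis=0) - s * rp.mean(axis=0)
    return s, t


def _overlap_score(pre_mask: np.ndarray, post_pts: np.ndarray,
                   transform: SimilarityTransform2D) -> float:
    """Mean (bilinear) pre-mask value at the transformed post foreground."""
    mapped = transform.apply(post_pts)
    # map_coordinates indexes (row, col) = (y, x)
    vals = ndimage.map_coordinates(pre_mask.astype(float),
                                   [mapped[:, 1], mapped[:, 0]],
                                   order=1, mode="constant", cval=0.0)
    return float(vals.mean())


def fit_similarity_transform(pre_points: np.ndarray, post_points: np.ndarray,
                             pre_mask: np.ndarray | None = None,
                             post_mask: np.ndarray | None = None,
                             rotation_range_deg: float = 20.0,
                             grid_step_deg: float = 1.0,
                             refine_tol_deg: float = 0.05,
                             max_sample_points: int = 25000) -> SimilarityTransform2D:
    """Recover the post-to-pre similarity transform.

    Scale and translation come from a least-squares fit on the marked
    corresponding point pairs with the rotation held fixed; the rotation is
    then chosen to maximize mask overlap, scanned on a coarse grid over
    ``+-rotation_range_deg`` and refined by golden-section search well
    below 0.1 degrees.  Without masks the rotation stays at zero.
    """
    pre = np.asarray(pre_points, dtype=float).reshape(-1, 2)
    post = np.asarray(post_points, dtype=float).reshape(-1, 2)
    if len(pre) != len(post):
        raise UnderdeterminedTransformError("point lists differ in length")
    if len(pre) < 2:
        raise UnderdeterminedTransformError(
            f"need >= 2 corresponding point pairs, got {len(pre)}")

    def build(theta: float) -> SimilarityTransform2D:
        s, t = _fit_scale_translation(pre, post, theta)
        return SimilarityTransform2D(s, theta, (float(t[0]), float(t[1])))

    if pre_mask is None or post_mask is None:
        return build(0.0)

    post_fg = np.argwhere(np.asarray(post_mask) > 0)[:, ::-1].astype(float)  # (x, y)
    if len(post_fg) == 0:
        raise TemplatingError("post mask has no foreground")
    if len(post_fg) > max_sample_points:
        step = len(post_fg) // max_sample_points
        post_fg = post_fg[::step]
    pre_arr = np.asarray(pre_mask, dtype=float)

    def score(theta: float) -> float:
        return _overlap_score(pre_arr, post_fg, build(theta))

    grid = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9,
                     grid_step_deg)
    scores = [score(th) for th in grid]
    best = int(np.argmax(scores))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]

    # golden-section maximization on [lo, hi]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = float(lo), float(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = score(c), score(d)
    while b - a > refine_tol_deg:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = score(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = score(d)
    theta = (a + b) / 2.0
    return build(theta)


# ---------------------------------------------------------------------------
# positioning error


def _baseline(p: Point2, q: Point2) -> DirectedLine:
    return DirectedLine.through(p, q)


def _midpoint(p: Point2, q: Point2) -> Point2:
    return Point2((p.x + q.x) / 2.0, (p.y + q.y) / 2.0)


def positioning_error(result, postop_points: dict,
                      transform: SimilarityTransform2D) -> dict:
    """Position and alignment error per component and view.

    ``postop_points`` holds, per view and component, the two manually
    marked implant edge points in the postoperative frame, e.g.
    ``{"AP": {"femoral": {"medial": [x, y], "lateral": [x, y]}, ...},
    "LAT": {"femoral": {"anterior": ..., "posterior": ...}, ...}}``.

    Position error uses the insert-point midpoint, except for the lateral
    femoral component where the most posterior implant point's offset from
    the anterior cortical line is compared.  Alignment error is the angle
    between the predicted reference line (resection line; anterior
    cortical line for the lateral femur) and the marked implant baseline.
    """
    cor = result.coronal_plan
    sag = result.sagittal_plan
    out: dict[str, dict[str, dict[str, float]]] = {}

    def marked(view: str, comp: str) -> tuple[Point2, Point2]:
        try:
            d = postop_points[view][comp]
            names = list(d)
            p, q = d[names[0]], d[names[1]]
        except (KeyError, IndexError):
            raise TemplatingError(
                f"missing marked implant points for {view}/{comp}") from None
        return (Point2(float(p[0]), float(p[1])),
                Point2(float(q[0]), float(q[1])))

    def entry(view: str, comp: str, pred_line: DirectedLine,
              pred_ref: Point2, mode: str) -> dict[str, float]:
        p, q = marked(view, comp)
        p, q = transform.apply(p), transform.apply(q)
        base = _baseline(p, q)
        if mode == "midpoint":
            pos = pred_ref.distance_to(_midpoint(p, q))
        else:  # most-posterior point, offset from the anterior cortical line
            line = sag.anterior_cortical_line
            post_pt = max((p, q), key=lambda r: abs(line.signed_distance(r)))
            pos = abs(abs(line.signed_distance(post_pt))
                      - abs(line.signed_distance(sag.femoral_posterior_point)))
        return {"position_error_mm": float(pos),
                "alignment_error_deg": float(angle_between_deg(pred_line, base))}

    out["AP"] = {
        "femoral": entry("AP", "femoral", cor.femoral_resection,
                         _midpoint(*cor.femoral_insert_points), "midpoint"),
        "tibial": entry("AP", "tibial", cor.tibial_resection,
                        _midpoint(*cor.tibial_insert_points), "midpoint"),
    }
    out["LAT"] = {
        "femoral": entry("LAT", "femoral", sag.anterior_cortical_line,
                         sag.femoral_posterior_point, "posterior"),
        "tibial": entry("LAT", "tibial", sag.tibial_resection,
                        _midpoint(*sag.tibial_insert_points), "midpoint"),
    }
    return out
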