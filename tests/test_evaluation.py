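"""Agreement taxonomy, weighted kappa, registration, positioning error."""

import math

import numpy as np
import pytest

from kneetemplate.errors import (TemplatingError, UndefinedKappaError,
                                 UnderdeterminedTransformError)
from kneetemplate.evaluation import (SimilarityTransform2D, agreement_summary,
                                     classify_prediction,
                                     fit_similarity_transform,
                                     kappa_reliability_band,
                                     positioning_error,
                                     quadratic_weighted_kappa)
from kneetemplate.geometry import Point2


def brute_force_kappa(pred, act, cats):
    """Direct double-sum evaluation of the quadratic-weighted formula."""
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    n = len(pred)
    O = np.zeros((k, k))
    for p, a in zip(pred, act):
        O[idx[p], idx[a]] += 1 / n
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (i - j) ** 2 / (k - 1) ** 2
            num += w * O[i, j]
            den += w * O[i].sum() * O[:, j].sum()
    return 1 - num / den


class TestClassification:
    @pytest.mark.parametrize("pred,act,cat", [
        (4, 4, "exact"),
        (5, 4, "accurate"),
        (3, 4, "accurate"),
        (6, 4, "overestimate"),
        (2, 4, "underestimate"),
    ])
    def test_taxonomy(self, pred, act, cat):
        assert classify_prediction(pred, act) == cat

    def test_partition_of_integer_deltas(self):
        for delta in range(-6, 7):
            cat = classify_prediction(4 + delta, 4)
            assert cat in {"exact", "accurate", "overestimate", "underestimate"}


class TestAgreementSummary:
    def test_cohort_percentages(self):
        """32 exact + 40 within-one of 81 -> 39.5% exact, 88.9% accurate."""
        records = ([(4, 4)] * 32 + [(5, 4)] * 40 + [(6, 4)] * 2 + [(2, 4)] * 7)
        s = agreement_summary(records)
        assert s["n"] == 81
        assert s["exact"] == 32 and s["exact_pct"] == 39.5
        assert s["accurate"] == 72 and s["accurate_pct"] == 88.9

    def test_all_exact(self):
        s = agreement_summary([(3, 3)] * 10)
        assert s["exact_pct"] == 100.0
        assert s["accurate_pct"] == 100.0
        assert s["overestimate"] == s["underestimate"] == 0

    def test_counts_partition(self):
        rng = np.random.default_rng(0)
        records = list(zip(rng.integers(1, 9, 50), rng.integers(1, 9, 50)))
        s = agreement_summary(records)
        inaccurate = s["overestimate"] + s["underestimate"]
        assert s["accurate"] + inaccurate == s["n"]
        assert s["exact"] <= s["accurate"]

    def test_empty_raises(self):
        with pytest.raises(TemplatingError):
            agreement_summary([])


class TestQuadraticKappa:
    def test_perfect_agreement(self):
        labels = [1, 2, 3, 4, 2, 3, 1, 4]
        assert quadratic_weighted_kappa(labels, labels) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cats = list(range(1, 5))
        pred = rng.choice(cats, 60).tolist()
        act = rng.choice(cats, 60).tolist()
        kappa = quadratic_weighted_kappa(pred, act, cats)
        assert kappa == pytest.approx(brute_force_kappa(pred, act, cats),
                                      abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(12)
        pred = rng.choice([1, 2, 3, 4, 5], 200).tolist()
        act = np.clip(np.array(pred) + rng.choice([-1, 0, 0, 1], 200),
                      1, 5).tolist()
        ours = quadratic_weighted_kappa(pred, act, [1, 2, 3, 4, 5])
        ref = cohen_kappa_score(pred, act, labels=[1, 2, 3, 4, 5],
                                weights="quadratic")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        pred = rng.choice([1, 2, 3], 40).tolist()
        act = rng.choice([1, 2, 3], 40).tolist()
        k1 = quadratic_weighted_kappa(pred, act, [1, 2, 3])
        order = rng.permutation(40)
        k2 = quadratic_weighted_kappa([pred[i] for i in order],
                                      [act[i] for i in order], [1, 2, 3])
        assert k1 == pytest.approx(k2, abs=1e-15)

    def test_degenerate_raises(self):
        with pytest.raises(UndefinedKappaError):
            quadratic_weighted_kappa([2, 2, 2], [2, 2, 2])

    def test_reliability_bands(self):
        assert kappa_reliability_band(0.60) == "moderate"
        assert kappa_reliability_band(0.70) == "substantial"
        assert kappa_reliability_band(0.9) == "almost perfect"
        assert kappa_reliability_band(-0.1) == "poor"


def make_masks(shape=(260, 260)):
    """An asymmetric bone-like blob and helper to rasterize transforms."""
    from skimage.draw import polygon as draw_polygon

    base = np.array([[60, 40], [150, 50], [180, 90], [170, 160], [120, 200],
                     [70, 180], [50, 110]], dtype=float)  # (x, y)

    def rasterize(pts):
        mask = np.zeros(shape, dtype=np.uint8)
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
        mask[rr, cc] = 1
        return mask

    return base, rasterize


class TestSimilarityTransform:
    def test_identity(self):
        pts = np.array([[10.0, 10.0], [50.0, 30.0], [20.0, 60.0]])
        tf = fit_similarity_transform(pts, pts)
        assert tf.scale == pytest.approx(1.0)
        assert tf.rotation_deg == 0.0
        assert np.allclose(tf.translation, (0, 0), atol=1e-9)

    def test_scale_translation_recovery_points_only(self):
        pre = np.array([[10.0, 10.0], [50.0, 30.0], [20.0, 60.0]])
        post = (pre - np.array([5.0, -3.0])) / 1.2
        tf = fit_similarity_transform(pre, post)
        assert tf.scale == pytest.approx(1.2, abs=1e-9)
        assert np.allclose(tf.translation, (5.0, -3.0), atol=1e-9)

    @pytest.mark.parametrize("rot", [7.0, -11.0])
    def test_rotation_recovery_with_masks(self, rot):
        base, rasterize = make_masks()
        pre_mask = rasterize(base)
        tf_true = SimilarityTransform2D(1.0 / 1.1, -rot, (0.0, 0.0))
        # post frame = inverse mapping of pre; pick translation so the post
        # blob stays inside the canvas
        post_pts = tf_true.apply(base)
        post_pts += np.array([20.0, 15.0])
        post_mask = rasterize(post_pts)
        marked = base[[0, 2, 4]]
        marked_post = tf_true.apply(marked) + np.array([20.0, 15.0])
        tf = fit_similarity_transform(marked, marked_post, pre_mask, post_mask)
        assert tf.rotation_deg == pytest.approx(rot, abs=0.3)
        assert tf.scale == pytest.approx(1.1, abs=0.01)
        # the fitted map must send marked post points back onto pre points
        assert np.allclose(tf.apply(marked_post), marked, atol=0.5)

    def test_underdetermined_raises(self):
        with pytest.raises(UnderdeterminedTransformError):
            fit_similarity_transform(np.array([[0.0, 0.0]]),
                                     np.array([[1.0, 1.0]]))


class TestPositioningError:
    @pytest.fixture
    def templated(self, noiseless_knee):
        from kneetemplate.sizing import template_knee
        _, ap, lat = noiseless_knee(seed=20)
        return template_knee(ap, lat)

    @staticmethod
    def postop_from_result(result, displace=(0.0, 0.0), rotate_deg=0.0):
        """Marked points constructed exactly at (or displaced from) the
        predicted insert points."""
        cor, sag = result.coronal_plan, result.sagittal_plan

        def shift_rot(pair, line):
            pts = np.array([[p.x, p.y] for p in pair])
            if rotate_deg:
                mid = pts.mean(axis=0)
                th = math.radians(rotate_deg)
                R = np.array([[math.cos(th), -math.sin(th)],
                              [math.sin(th), math.cos(th)]])
                pts = (pts - mid) @ R.T + mid
            return pts + np.asarray(displace)

        f_ap = shift_rot(cor.femoral_insert_points, cor.femoral_resection)
        t_ap = shift_rot(cor.tibial_insert_points, cor.tibial_resection)
        t_lat = shift_rot(sag.tibial_insert_points, sag.tibial_resection)
        post = sag.femoral_posterior_point
        line = sag.anterior_cortical_line
        f_lat = np.array([[post.x, post.y],
                          [line.origin.x, line.origin.y]]) + np.asarray(displace)
        return {
            "AP": {"femoral": {"medial": f_ap[0].tolist(),
                               "lateral": f_ap[1].tolist()},
                   "tibial": {"medial": t_ap[0].tolist(),
                              "lateral": t_ap[1].tolist()}},
            "LAT": {"femoral": {"posterior": f_lat[0].tolist(),
                                "flange": f_lat[1].tolist()},
                    "tibial": {"anterior": t_lat[0].tolist(),
                               "posterior": t_lat[1].tolist()}},
        }

    def test_identity_gives_zero_errors(self, templated):
        identity = SimilarityTransform2D(1.0, 0.0, (0.0, 0.0))
        errs = positioning_error(templated,
                                 self.postop_from_result(templated), identity)
        for view in ("AP", "LAT"):
            for comp in ("femoral", "tibial"):
                assert errs[view][comp]["position_error_mm"] == pytest.approx(
                    0.0, abs=1e-9)
        assert errs["AP"]["femoral"]["alignment_error_deg"] == pytest.approx(
            0.0, abs=1e-9)

    def test_displacement_along_resection_measured(self, templated):
        cor = templated.coronal_plan
        d = np.array(cor.femoral_resection.direction) * 4.0
        postop = self.postop_from_result(templated, displace=tuple(d))
        identity = SimilarityTransform2D(1.0, 0.0, (0.0, 0.0))
        errs = positioning_error(templated, postop, identity)
        assert errs["AP"]["femoral"]["position_error_mm"] == pytest.approx(
            4.0, abs=1e-9)

    def test_baseline_rotation_measured(self, templated):
        postop = self.postop_from_result(templated, rotate_deg=2.0)
        identity = SimilarityTransform2D(1.0, 0.0, (0.0, 0.0))
        errs = positioning_error(templated, postop, identity)
        assert errs["AP"]["tibial"]["alignment_error_deg"] == pytest.approx(
            2.0, abs=1e-6)

    def test_missing_points_raise(self, templated):
        identity = SimilarityTransform2D(1.0, 0.0, (0.0, 0.0))
        with pytest.raises(TemplatingError):
            positioning_error(templated, {"AP": {}}, identity)
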