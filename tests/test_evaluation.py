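"""CNR, edge maps, batch statistics, HU stability."""

import numpy as np
import pytest

from mvct_enhance import (CTImage, ROISpec, ValidationError, batch_cnr, cnr,
                          edge_map, hu_stability)


def _two_roi_image(target_vals, background_vals):
    """16x32 image: target values tile the left 8x8 box, background the right."""
    img = np.zeros((16, 32))
    t = np.resize(np.asarray(target_vals, float), (8, 8))
    b = np.resize(np.asarray(background_vals, float), (8, 8))
    img[4:12, 4:12] = t
    img[4:12, 20:28] = b
    target = ROISpec("rectangle", (8, 8), extents=(8, 8), role="target")
    background = ROISpec("rectangle", (8, 24), extents=(8, 8), role="background")
    return img, target, background


class TestCNR:
    def test_closed_form_example(self):
        # means 100/50, population sds 10/10 -> 2*50/sqrt(200) = 7.0711
        img, t, b = _two_roi_image([90, 110], [40, 60])
        r = cnr(img, t, b)
        assert r.mean_target == 100 and r.mean_background == 50
        assert r.sd_target == 10 and r.sd_background == 10
        assert r.cnr == pytest.approx(7.0711, abs=1e-4)

    def test_identical_rois_give_zero(self):
        img, t, b = _two_roi_image([5.0], [5.0])
        assert cnr(img, t, b).cnr == 0.0

    def test_symmetric_under_roi_swap(self, rng):
        img, t, b = _two_roi_image(rng.normal(10, 3, 64), rng.normal(0, 2, 64))
        assert cnr(img, t, b).cnr == pytest.approx(cnr(img, b, t).cnr)

    def test_affine_invariance(self, rng):
        img, t, b = _two_roi_image(rng.normal(10, 3, 64), rng.normal(0, 2, 64))
        base = cnr(img, t, b).cnr
        assert cnr(img + 37.0, t, b).cnr == pytest.approx(base)
        assert cnr(img * 2.5, t, b).cnr == pytest.approx(base)

    def test_overlapping_rois_rejected(self):
        img = np.zeros((16, 16))
        a = ROISpec("circle", (8, 8), radius=4)
        b = ROISpec("circle", (9, 9), radius=4)
        with pytest.raises(ValidationError):
            cnr(img, a, b)

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            ROISpec("circle", (2, 2), radius=5).mask((16, 16))

    def test_tiny_roi_rejected(self):
        with pytest.raises(ValidationError):
            ROISpec("circle", (8, 8), radius=1.2).mask((16, 16))


class TestEdgeMap:
    def test_constant_image_has_no_edges(self):
        edges, count = edge_map(np.full((32, 32), 50.0))
        assert count == 0 and not edges.any()

    def test_step_edge_detected_as_thin_line(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 200.0
        edges, count = edge_map(img)
        cols = np.flatnonzero(edges[16])
        # a symmetric discrete step yields a 1-2 px line at the boundary
        assert 1 <= len(cols) <= 2 and all(abs(c - 16) <= 1 for c in cols)
        assert edges[4:28, cols[0]].all()  # line runs along the step

    def test_depends_only_on_inputs(self, rng):
        img = rng.normal(0, 30, (32, 32))
        a = edge_map(img)[0]
        b = edge_map(img)[0]
        assert np.array_equal(a, b)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            edge_map(np.zeros((16, 16)), low=0.3, high=0.2)


class TestBatchCNR:
    def _pair_with_cnr_shift(self, rng, delta):
        """original/enhanced pair whose CNR difference is exactly delta/10ish:
        target mean raised, sds held at 10 by an alternating pattern."""
        img, t, b = _two_roi_image([90, 110], [40, 60])
        enh = img.copy()
        # raising the target mean by 5*sqrt(2)*delta raises CNR by delta
        enh[4:12, 4:12] += 5.0 * np.sqrt(2.0) * delta
        return (CTImage(img + 1000), CTImage(enh + 1000)), t, b

    def test_identical_arms_reported_as_no_difference(self):
        img, t, b = _two_roi_image([90, 110], [40, 60])
        out = batch_cnr([(CTImage(img + 1000), CTImage(img.copy() + 1000))] * 3, t, b)
        assert out["t"] == 0.0 and out["p"] == 1.0
        assert out["note"] == "no difference"

    def test_uniform_positive_shift_gives_large_positive_t(self, rng):
        deltas = 1.0 + rng.normal(0, 0.01, 6)
        pairs = []
        for d in deltas:
            pair, t, b = self._pair_with_cnr_shift(rng, d)
            pairs.append(pair)
        out = batch_cnr(pairs, t, b)
        assert out["t"] > 10

    def test_t_statistic_matches_paired_closed_form(self, rng):
        deltas = np.array([0.8, 1.3, 0.9, 1.6, 1.1])
        pairs = []
        for d in deltas:
            pair, t, b = self._pair_with_cnr_shift(rng, d)
            pairs.append(pair)
        out = batch_cnr(pairs, t, b)
        d = np.array([cnr(q.pixels, t, b).cnr - cnr(p.pixels, t, b).cnr
                      for p, q in pairs])
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out["t"] == pytest.approx(expected, rel=1e-10)

    def test_fewer_than_two_pairs_rejected(self):
        img, t, b = _two_roi_image([1.0], [0.0])
        with pytest.raises(ValidationError):
            batch_cnr([(CTImage(img), CTImage(img))], t, b)


class TestHUStability:
    def test_identical_images_report_zero(self):
        img = np.full((32, 32), 40.0)
        roi = ROISpec("circle", (16, 16), radius=5)
        rep = hu_stability(img, img.copy(), [roi])
        assert rep.roi_mean_diff == [0.0]
        assert rep.rms_diff == 0.0 and rep.max_abs_diff == 0.0

    def test_constant_shift_reported_exactly(self):
        img = np.full((32, 32), 40.0)
        roi = ROISpec("circle", (16, 16), radius=5)
        rep = hu_stability(img, img + 3.0, [roi])
        assert rep.roi_mean_diff == [pytest.approx(3.0)]
        assert rep.rms_diff == pytest.approx(3.0)
        assert rep.max_abs_diff == pytest.approx(3.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            hu_stability(np.zeros((8, 8)), np.zeros((9, 9)), [])
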