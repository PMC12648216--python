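"""Mask preprocessing, coverage filtering, representative selection, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from raic.consensus import (
    AnnotationSet,
    coverage_filter,
    grid_fleiss_kappa,
    mask_scores,
    preprocess_mask,
    roi_geometry,
    select_representative,
)
from raic.reliability import fleiss_kappa_from_counts


def ellipse_mask(shape, cx, cy, a, b, theta=0.0):
    h, w = shape
    Y, X = np.mgrid[0:h, 0:w]
    u = (X - cx) * np.cos(theta) + (Y - cy) * np.sin(theta)
    v = -(X - cx) * np.sin(theta) + (Y - cy) * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestPreprocess:
    def test_small_speck_removed(self):
        m = ellipse_mask((200, 200), 100, 100, 40, 30)
        m[5, 5] = m[5, 6] = m[6, 5] = True  # 3-px speck
        out = preprocess_mask(m, min_blob_px=10)
        assert not out[5, 5]
        assert out[100, 100]

    def test_interior_hole_filled(self):
        m = ellipse_mask((200, 200), 100, 100, 40, 30)
        m[100, 100] = False
        out = preprocess_mask(m, opening_radius=0)
        assert out[100, 100]
        assert out.sum() == m.sum() + 1

    def test_clean_mask_unchanged(self):
        m = ellipse_mask((200, 200), 100, 100, 50, 35)
        out = preprocess_mask(m)
        assert np.array_equal(out, preprocess_mask(out))

    def test_empty_result_warns(self):
        m = np.zeros((50, 50), dtype=bool)
        m[10, 10] = True
        with pytest.warns(UserWarning):
            out = preprocess_mask(m, min_blob_px=10)
        assert not out.any()


class TestCoverageFilter:
    @staticmethod
    def masks_with_coverage(fracs, shape=(100, 100)):
        out = {}
        for i, f in enumerate(fracs):
            m = np.zeros(shape, dtype=bool)
            m.ravel()[: int(round(f * m.size))] = True
            out[f"e{i + 1}"] = m
        return out

    def test_both_rules_fire_on_outlier(self):
        masks = self.masks_with_coverage([0.10, 0.12, 0.14, 0.60])
        kept, log = coverage_filter(masks)
        assert set(kept) == {"e1", "e2", "e3"}
        assert log[0]["expert_id"] == "e4"
        assert "coverage>0.5" in log[0]["rules"]
        assert "coverage>1.5*median" in log[0]["rules"]

    def test_borderline_kept(self):
        # median 0.13; 1.5x = 0.195 >= 0.19, and 0.19 <= 0.5 -> keep all
        masks = self.masks_with_coverage([0.10, 0.12, 0.14, 0.19])
        kept, log = coverage_filter(masks)
        assert set(kept) == {"e1", "e2", "e3", "e4"} and log == []

    def test_single_mask_is_its_own_median(self):
        masks = self.masks_with_coverage([0.30])
        kept, log = coverage_filter(masks)
        assert set(kept) == {"e1"} and log == []

    def test_all_excluded_raises(self):
        masks = self.masks_with_coverage([0.7, 0.8])
        with pytest.raises(ValueError):
            coverage_filter(masks)

    @given(st.lists(st.floats(0.01, 0.45), min_size=1, max_size=6))
    @settings(max_examples=25, deadline=None)
    def test_never_removes_below_both_thresholds(self, fracs):
        masks = self.masks_with_coverage(fracs, shape=(40, 40))
        med = np.median([float(m.mean()) for m in masks.values()])
        kept, _ = coverage_filter(masks)
        for eid, m in masks.items():
            if float(m.mean()) <= min(0.5, 1.5 * med):
                assert eid in kept


class TestMaskScores:
    def test_identical_masks_score_one(self):
        m = ellipse_mask((50, 50), 25, 25, 10, 8)
        s = mask_scores(m, m)
        assert s["f1"] == s["iou"] == s["dice"] == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((20, 20), dtype=bool); a[:5] = True
        b = np.zeros((20, 20), dtype=bool); b[10:] = True
        s = mask_scores(a, b)
        assert s["f1"] == s["iou"] == s["dice"] == 0.0

    def test_hand_computed_half_overlap(self):
        a = np.zeros((20, 20), dtype=bool); a.ravel()[:100] = True
        b = np.zeros((20, 20), dtype=bool); b.ravel()[50:150] = True
        s = mask_scores(a, b)
        assert s["iou"] == pytest.approx(1 / 3)
        assert s["dice"] == s["f1"] == pytest.approx(1 / 2)

    def test_both_empty_degenerate(self):
        z = np.zeros((5, 5), dtype=bool)
        s = mask_scores(z, z)
        assert s["dice"] == 1.0 and s["degenerate"]

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mask_scores(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_dice_equals_f1_and_iou_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((15, 15)) < rng.uniform(0.1, 0.9)
        b = rng.random((15, 15)) < rng.uniform(0.1, 0.9)
        s = mask_scores(a, b)
        assert s["dice"] == s["f1"]
        assert s["dice"] == pytest.approx(2 * s["iou"] / (1 + s["iou"]), abs=1e-12)


def _square(canvas, x0, y0, size, label):
    m = np.zeros(canvas, dtype=np.uint8)
    m[y0:y0 + size, x0:x0 + size] = label
    return m


def _annotation_fixture():
    """4 experts around two square ROIs; expert 2 is the planted argmax.

    e2 draws exactly the strict-majority shape M: e1 and e3 each add a
    different spurious blob (majority vote cancels them), e4 misses a chunk
    of M (outvoted by e1+e3). Hence F1(e2 vs its LOO consensus) = 1 uniquely.
    """
    canvas = (120, 160)  # (h, w)
    base = np.zeros(canvas, dtype=np.uint8)
    base[20:60, 20:60] = 1
    base[70:110, 90:130] = 2
    masks = {"e2": base.copy()}
    e1 = base.copy(); e1[80:100, 10:30] = 2   # extra blob merged into ROI 2's label
    e3 = base.copy(); e3[10:25, 120:140] = 1  # different extra blob
    e4 = base.copy(); e4[20:35, 20:35] = 0    # missing chunk of ROI 1
    masks.update({"e1": e1, "e3": e3, "e4": e4})
    return AnnotationSet(image_id="fx", canvas=(160, 120), masks=masks)


class TestSelectRepresentative:
    def test_planted_argmax_f1_selected(self):
        ann = _annotation_fixture()
        egp, rep = select_representative(ann, preprocess=False)
        assert rep["representative"] == "e2"
        assert egp.n_states == 2

    def test_tie_break_prefers_higher_roi_count(self):
        # two pairs of identical masks -> F1 ties; e3/e4 carry an extra ROI
        canvas = (120, 160)
        two = np.zeros(canvas, dtype=np.uint8)
        two[20:60, 20:60] = 1
        two[70:110, 90:130] = 2
        three = two.copy()
        three[20:50, 100:130] = 3
        masks = {"e1": two, "e2": two.copy(), "e3": three, "e4": three.copy()}
        ann = AnnotationSet(image_id="tie", canvas=(160, 120), masks=masks)
        egp, rep = select_representative(ann, preprocess=False)
        assert rep["representative"] in {"e3", "e4"}
        assert rep["representative_roi_count"] == 3

    def test_fewer_than_two_experts_raises(self):
        canvas = (120, 160)
        masks = {"e1": _square(canvas, 10, 10, 30, 1)}
        ann = AnnotationSet(image_id="solo", canvas=(160, 120), masks=masks)
        with pytest.raises(ValueError):
            select_representative(ann, preprocess=False)

    def test_permutation_invariant_in_expert_order(self):
        ann = _annotation_fixture()
        rev = AnnotationSet(
            image_id="fx", canvas=(160, 120),
            masks=dict(reversed(list(ann.masks.items()))),
        )
        _, rep_a = select_representative(ann, preprocess=False)
        _, rep_b = select_representative(rev, preprocess=False)
        assert rep_a["representative"] == rep_b["representative"]


class TestGridFleiss:
    def test_identical_masks_give_kappa_one(self):
        m = ellipse_mask((108, 192), 96, 54, 40, 25)
        out = grid_fleiss_kappa({"a": m, "b": m, "c": m}, grid=(8, 16))
        assert out["fleiss_kappa"] == 1.0
        assert out["consensus_all_ratio"] == pytest.approx(float((
            grid_fleiss_kappa({"a": m, "b": m}, grid=(8, 16))["consensus_all_ratio"])))

    def test_two_rater_hand_value(self):
        # 4 cells, ratings A:1100 B:0011 -> closed-form Fleiss kappa
        counts = np.array([[1, 1], [1, 1], [1, 1], [1, 1]])
        kappa, flag = fleiss_kappa_from_counts(counts)
        # P_bar = 0, P_e = 0.5 -> kappa = -1
        assert kappa == pytest.approx(-1.0)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(3)
        # sparse masks so cells genuinely vary across raters
        masks = {f"e{i}": rng.random((54, 96)) < 0.01 for i in range(4)}
        out = grid_fleiss_kappa(masks, grid=(6, 12))
        grids = np.stack([
            (np.add.reduceat(np.add.reduceat(m.astype(int), np.arange(0, 54, 9), axis=0),
                             np.arange(0, 96, 8), axis=1) > 0).ravel()
            for _, m in sorted(masks.items())
        ])
        marked = grids.sum(axis=0)
        table = np.column_stack([marked, 4 - marked])
        assert out["fleiss_kappa"] == pytest.approx(sm_fleiss(table), abs=1e-12)

    def test_sensitivity_entries_present(self):
        rng = np.random.default_rng(4)
        masks = {f"e{i}": rng.random((108, 192)) < 0.25 for i in range(4)}
        out = grid_fleiss_kappa(masks, sensitivity=True)
        grids = {e["grid"] for e in out["sensitivity"]}
        assert grids == {"24x48", "16x32", "32x64"}
        assert any(e["threshold"] == 0.2 for e in out["sensitivity"])


class TestRoiGeometry:
    def test_axis_aligned_ellipse_moments(self):
        m = ellipse_mask((200, 300), 100, 50, 40, 20).astype(np.uint8)
        rois = roi_geometry(m)
        r = rois[0]
        assert r.cx == pytest.approx(100, abs=0.5)
        assert r.cy == pytest.approx(50, abs=0.5)
        assert r.major_axis_length == pytest.approx(80, rel=0.03)
        assert r.minor_axis_length == pytest.approx(40, rel=0.03)
        assert r.orientation == pytest.approx(0.0, abs=0.02)

    def test_circle_orientation_zero_by_convention(self):
        m = ellipse_mask((200, 200), 100, 100, 30, 30).astype(np.uint8)
        r = roi_geometry(m)[0]
        assert r.major_axis_length == pytest.approx(r.minor_axis_length, rel=0.02)
        assert r.orientation == 0.0

    def test_rotated_ellipse_orientation(self):
        m = ellipse_mask((400, 400), 200, 200, 80, 30, theta=np.pi / 4).astype(np.uint8)
        r = roi_geometry(m)[0]
        assert r.orientation == pytest.approx(np.pi / 4, abs=0.02)

    def test_empty_label_raises(self):
        m = np.zeros((50, 50), dtype=np.uint8)
        m[10:20, 10:20] = 2  # label 1 missing
        with pytest.raises(ValueError, match="label 1"):
            roi_geometry(m)
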