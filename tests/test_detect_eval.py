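"""3D IoU, NMS, matching and COCO-style AP against brute-force oracles."""

import numpy as np
import pytest

from _oracles import average_precision_oracle, voxel_count_iou
from conftest import random_int_box
from rootalign.detect_eval import (
    DetectorConfig,
    MatchCounts,
    average_precision,
    baseline_detector,
    evaluate,
    iou3d,
    map_range,
    match_detections,
    nms,
    precision_recall_f1,
)
from rootalign.errors import ContractViolationError, UndefinedAPError
from rootalign.io_formats import Box3D, Detection, Volume, world_to_voxel
from rootalign.phantom import Distractor, PhantomSpec, make_phantom


def _box(lo, hi, space="voxel"):
    return Box3D(lo=np.asarray(lo, float), hi=np.asarray(hi, float), space=space)


def _det(lo, hi, conf):
    return Detection(box=_box(lo, hi), confidence=conf)


class TestIoU3D:
    def test_identical_boxes(self):
        b = _box([0, 0, 0], [10, 10, 10])
        assert iou3d(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou3d(_box([0, 0, 0], [5, 5, 5]), _box([6, 6, 6], [9, 9, 9])) == 0.0

    def test_half_shifted_cubes(self):
        # [0,10)^3 vs [5,15)^3: intersection 5^3 = 125, union 2*1000 - 125
        val = iou3d(_box([0, 0, 0], [10, 10, 10]), _box([5, 5, 5], [15, 15, 15]))
        assert val == pytest.approx(125 / 1875, abs=1e-15)

    def test_symmetry_and_bounds_random(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a, b = random_int_box(rng, 20), random_int_box(rng, 20)
            v = iou3d(a, b)
            assert 0.0 <= v <= 1.0
            assert v == iou3d(b, a)

    def test_matches_voxel_counting_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a, b = random_int_box(rng, 40), random_int_box(rng, 40)
            oracle = voxel_count_iou(
                a.lo.astype(int), a.hi.astype(int), b.lo.astype(int), b.hi.astype(int), 40
            )
            assert abs(iou3d(a, b) - oracle) < 1e-12

    def test_space_mismatch_rejected(self):
        with pytest.raises(ContractViolationError):
            iou3d(_box([0, 0, 0], [1, 1, 1]), _box([0, 0, 0], [1, 1, 1], space="world"))


class TestNMS:
    def test_suppresses_overlapping_lower_confidence(self):
        dets = [_det([0, 0, 0], [10, 10, 10], 0.9), _det([1, 0, 0], [11, 10, 10], 0.8)]
        assert iou3d(dets[0].box, dets[1].box) > 0.5
        kept = nms(dets)
        assert len(kept) == 1 and kept[0].confidence == 0.9

    def test_disjoint_detections_both_kept(self):
        dets = [_det([0, 0, 0], [5, 5, 5], 0.9), _det([20, 20, 20], [25, 25, 25], 0.9)]
        assert len(nms(dets)) == 2

    def test_confidence_filter_and_suppression_together(self):
        dets = [
            _det([0, 0, 0], [10, 10, 10], 0.9),
            _det([1, 1, 0], [11, 11, 10], 0.6),  # overlaps the first above 0.5
            _det([30, 30, 30], [35, 35, 35], 0.4),  # below conf threshold
        ]
        kept = nms(dets, conf_threshold=0.5, iou_threshold=0.5)
        assert [d.confidence for d in kept] == [0.9]

    def test_empty_input(self):
        assert nms([]) == []

    def test_idempotent_on_random_sets(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            dets = [
                Detection(box=random_int_box(rng, 15), confidence=float(rng.uniform()))
                for _ in range(rng.integers(0, 10))
            ]
            once = nms(dets)
            assert nms(once) == once

    def test_confidence_tie_stable_input_order(self):
        a = _det([0, 0, 0], [10, 10, 10], 0.7)
        b = _det([1, 0, 0], [11, 10, 10], 0.7)
        kept = nms([a, b])
        assert kept == [a]


class TestMatching:
    def test_single_match(self):
        gt = _box([0, 0, 0], [10, 10, 10])
        det = _det([2, 0, 0], [12, 10, 10], 0.9)  # IoU 8/12 ~ 0.667
        counts, matched = match_detections([det], [gt], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
        assert matched[0] == pytest.approx(iou3d(det.box, gt))

    def test_one_to_one_constraint(self):
        gt = _box([0, 0, 0], [10, 10, 10])
        dets = [_det([1, 0, 0], [11, 10, 10], 0.9), _det([2, 0, 0], [12, 10, 10], 0.8)]
        counts, _ = match_detections(dets, [gt], 0.5)
        assert (counts.tp, counts.fp) == (1, 1)

    def test_greedy_confidence_order_documented_vs_optimal(self):
        # highest-confidence detection claims its best gt first, even when a
        # different assignment would yield more matches (COCO convention)
        gt1 = _box([0, 0, 0], [10, 10, 10])
        gt2 = _box([40, 0, 0], [50, 10, 10])
        det_hi = _det([2, 0, 0], [12, 10, 10], 0.7)   # IoU 0.667 with gt1 only
        det_lo = _det([1, 0, 0], [11, 10, 10], 0.6)   # IoU 0.818 with gt1 only
        counts, matched = match_detections([det_hi, det_lo], [gt1, gt2], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)
        assert matched[0] == pytest.approx(iou3d(det_hi.box, gt1))

    def test_all_unmatched(self):
        counts, matched = match_detections([], [_box([0, 0, 0], [1, 1, 1])], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 1)
        assert matched == [0.0]


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (99, 1, 1, (0.99, 0.99, 0.99)),
            (3, 1, 2, (0.75, 0.6, 2 / (1 / 0.75 + 1 / 0.6))),
            (0, 5, 5, (0.0, 0.0, 0.0)),
        ],
    )
    def test_arithmetic(self, tp, fp, fn, expected):
        p, r, f1, _ = precision_recall_f1(MatchCounts(tp, fp, fn))
        assert (p, r, f1) == pytest.approx(expected)

    def test_zero_over_zero_flagged(self):
        with pytest.warns(UserWarning):
            p, r, f1, degenerate = precision_recall_f1(MatchCounts(0, 0, 5))
        assert degenerate and p == 0.0 and r == 0.0


def _random_instance(rng, n_images=2, max_dets=6, max_gts=4, grid=20):
    dets_by_image, gts_by_image, flat = {}, {}, []
    total_gts = 0
    for img in range(n_images):
        image_id = f"im{img}"
        gts = [random_int_box(rng, grid) for _ in range(rng.integers(0, max_gts // n_images + 1))]
        n_det = rng.integers(0, max_dets // n_images + 1)
        dets = []
        for _ in range(n_det):
            if gts and rng.uniform() < 0.6:
                gt = gts[rng.integers(len(gts))]
                jitter = rng.integers(-2, 3, size=3).astype(float)
                lo = np.maximum(gt.lo + jitter, 0.0)
                hi = np.maximum(np.minimum(gt.hi + jitter, grid), lo + 1.0)
                box = Box3D(lo=lo, hi=hi, space="voxel")
            else:
                box = random_int_box(rng, grid)
            dets.append(Detection(box=box, confidence=float(rng.uniform())))
        dets_by_image[image_id] = dets
        gts_by_image[image_id] = gts
        total_gts += len(gts)
        flat += [
            (image_id, tuple(d.box.lo), tuple(d.box.hi), d.confidence) for d in dets
        ]
    return dets_by_image, gts_by_image, flat, total_gts


class TestAveragePrecision:
    def test_perfect_detector(self):
        gt = _box([0, 0, 0], [10, 10, 10])
        det = Detection(box=gt, confidence=0.9)
        assert average_precision({"a": [det]}, {"a": [gt]}, 0.5) == 1.0

    def test_total_miss(self):
        gt = _box([0, 0, 0], [10, 10, 10])
        det = _det([20, 20, 20], [22, 22, 22], 0.9)
        assert average_precision({"a": [det]}, {"a": [gt]}, 0.5) == 0.0

    def test_hit_miss_hit_matches_oracle(self):
        gt1, gt2 = _box([0, 0, 0], [10, 10, 10]), _box([20, 20, 20], [30, 30, 30])
        dets = [
            Detection(box=gt1, confidence=0.9),
            _det([50, 50, 50], [52, 52, 52], 0.8),
            Detection(box=gt2, confidence=0.7),
        ]
        ours = average_precision({"a": dets}, {"a": [gt1, gt2]}, 0.5)
        flat = [("a", tuple(d.box.lo), tuple(d.box.hi), d.confidence) for d in dets]
        oracle = average_precision_oracle(
            flat, {"a": [(tuple(gt1.lo), tuple(gt1.hi)), (tuple(gt2.lo), tuple(gt2.hi))]}, 0.5
        )
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_no_ground_truth_undefined(self):
        with pytest.raises(UndefinedAPError):
            average_precision({"a": []}, {"a": []}, 0.5)

    def test_random_instances_match_prefix_oracle(self):
        rng = np.random.default_rng(31)
        checked = 0
        for _ in range(100):
            dets_by_image, gts_by_image, flat, total_gts = _random_instance(rng)
            if total_gts == 0:
                continue
            gts_o = {
                img: [(tuple(g.lo), tuple(g.hi)) for g in gts]
                for img, gts in gts_by_image.items()
            }
            for threshold in (0.3, 0.5):
                ours = average_precision(dets_by_image, gts_by_image, threshold)
                oracle = average_precision_oracle(flat, gts_o, threshold)
                assert abs(ours - oracle) < 1e-12
            checked += 1
        assert checked >= 50

    def test_invariant_to_monotone_confidence_rescaling(self):
        rng = np.random.default_rng(32)
        dets_by_image, gts_by_image, _, total_gts = _random_instance(rng)
        while total_gts == 0 or not any(dets_by_image.values()):
            dets_by_image, gts_by_image, _, total_gts = _random_instance(rng)
        rescaled = {
            img: [Detection(box=d.box, confidence=d.confidence**3) for d in dets]
            for img, dets in dets_by_image.items()
        }
        assert average_precision(dets_by_image, gts_by_image, 0.5) == pytest.approx(
            average_precision(rescaled, gts_by_image, 0.5), abs=1e-12
        )

    def test_voc_all_points_mode_runs_and_bounds(self):
        rng = np.random.default_rng(33)
        dets_by_image, gts_by_image, _, total_gts = _random_instance(rng)
        while total_gts == 0:
            dets_by_image, gts_by_image, _, total_gts = _random_instance(rng)
        ap = average_precision(dets_by_image, gts_by_image, 0.5, interpolation="voc_all_points")
        assert 0.0 <= ap <= 1.0


class TestMapRange:
    def test_exact_detections_give_one_everywhere(self):
        gt = _box([0, 0, 0], [10, 10, 10])
        det = Detection(box=gt, confidence=1.0)
        map50, map50_95, per_iou = map_range({"a": [det]}, {"a": [gt]})
        assert map50 == 1.0 and map50_95 == 1.0
        assert all(v == 1.0 for v in per_iou.values())

    def test_iou_point_six_detections(self):
        # IoU = 0.6 exactly: AP 1 for thresholds <= 0.6, 0 above -> mean 0.3
        gt = _box([0, 0, 0], [10, 10, 10])
        det = _det([0, 0, 2.5], [10, 10, 12.5], 0.9)
        assert iou3d(det.box, gt) == pytest.approx(0.6)
        map50, map50_95, per_iou = map_range({"a": [det]}, {"a": [gt]})
        assert map50 == 1.0
        assert map50_95 == pytest.approx(0.3)

    def test_no_detections(self):
        map50, map50_95, _ = map_range({"a": []}, {"a": [_box([0, 0, 0], [1, 1, 1])]})
        assert map50 == 0.0 and map50_95 == 0.0

    def test_map5095_never_exceeds_map50(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            dets_by_image, gts_by_image, _, total_gts = _random_instance(rng)
            if total_gts == 0:
                continue
            map50, map50_95, _ = map_range(dets_by_image, gts_by_image)
            assert map50_95 <= map50 + 1e-12


class TestEvaluateReport:
    def test_report_consistency(self):
        gt = _box([0, 0, 0], [10, 10, 10])
        report = evaluate(
            {"a": [Detection(box=gt, confidence=0.9)], "b": []},
            {"a": [gt], "b": [gt]},
        )
        assert report.counts.tp == 1 and report.counts.fn == 1
        assert report.recall == pytest.approx(0.5)
        assert report.f1 == pytest.approx(
            2 * report.precision * report.recall / (report.precision + report.recall)
        )
        assert report.per_image_iou["a"] == 1.0 and report.per_image_iou["b"] == 0.0
        payload = report.to_dict()
        assert set(payload["counts"]) == {"tp", "fp", "fn"}
        assert len(payload["ap_per_iou"]) == 10


class TestBaselineDetector:
    def test_single_tube_detected_with_good_iou(self, noiseless_phantom):
        vol, truth = noiseless_phantom
        dets = baseline_detector(vol)
        assert dets and dets[0].confidence == 1.0
        roi_voxel = world_to_voxel(truth.roi_box, vol.affine)
        assert iou3d(dets[0].box, roi_voxel) >= 0.5

    def test_all_zero_volume_empty(self):
        vol = Volume(np.zeros((20, 20, 20)), np.eye(4))
        assert baseline_detector(vol) == []

    def test_two_structures_give_two_detections(self):
        spec = PhantomSpec(
            shape=(96, 96, 96),
            tube_angle_deg=60.0,
            tube_radius_mm=8.0,
            tube_length_mm=60.0,
            distractors=[Distractor("sphere", (30.0, 30.0, -30.0), 6.0, 500.0)],
        )
        vol, _ = make_phantom(spec)
        dets = baseline_detector(vol, DetectorConfig(min_voxels=20))
        assert len(dets) >= 2

    def test_normalized_volume_rejected(self, noiseless_phantom):
        vol, _ = noiseless_phantom
        from rootalign.preprocess import normalize_intensity

        with pytest.raises(ContractViolationError):
            baseline_detector(normalize_intensity(vol))
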