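"""Detection matching, precision/recall, AP and mAP."""

import numpy as np
import pytest

from leafdet.boxes import BoxXYXY
from leafdet.metrics import (
    Detection,
    GTRecord,
    average_precision,
    box_iou_xyxy,
    evaluate,
    match_detections,
    precision_recall,
)


def det(img, cls, conf, x1, y1, x2, y2):
    return Detection(img, cls, conf, BoxXYXY(x1, y1, x2, y2))


def gt(img, cls, x1, y1, x2, y2):
    return GTRecord(img, cls, BoxXYXY(x1, y1, x2, y2))


def reference_ap(flags, n_gt):
    """Independent AP oracle: enumerate the envelope pointwise."""
    if n_gt == 0 or len(flags) == 0:
        return 0.0
    tps = np.cumsum(flags)
    fps = np.cumsum([not f for f in flags])
    recalls = tps / n_gt
    precisions = tps / (tps + fps)
    ap = 0.0
    prev_r = 0.0
    for k in range(len(flags)):
        r = recalls[k]
        if r <= prev_r:
            continue
        # envelope at recall r: best precision at any rank with recall >= r
        p_env = max(precisions[j] for j in range(len(flags)) if recalls[j] >= r)
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


class TestMatching:
    def test_perfect_detections_all_tp(self):
        gts = [gt(0, 0, 0, 0, 10, 10), gt(0, 0, 20, 20, 30, 30)]
        dets = [det(0, 0, 1.0, 0, 0, 10, 10), det(0, 0, 1.0, 20, 20, 30, 30)]
        _, flags, fn = match_detections(dets, gts, 0.5)
        assert flags.all() and fn == 0

    def test_low_iou_is_fp_and_fn(self):
        gts = [gt(0, 0, 0, 0, 10, 10)]
        dets = [det(0, 0, 0.9, 5, 5, 16, 16)]  # IoU ~ 0.2
        _, flags, fn = match_detections(dets, gts, 0.5)
        assert not flags.any() and fn == 1

    def test_double_detection_consumes_gt_once(self):
        gts = [gt(0, 0, 0, 0, 10, 10)]
        dets = [
            det(0, 0, 0.9, 0, 0, 10, 9),   # IoU 0.9
            det(0, 0, 0.8, 0, 0, 10, 8),   # IoU 0.8
        ]
        ranked, flags, fn = match_detections(dets, gts, 0.5)
        assert list(flags) == [True, False] and fn == 0
        assert ranked[0].confidence == 0.9

    def test_class_and_image_must_match(self):
        gts = [gt(0, 1, 0, 0, 10, 10)]
        dets = [det(0, 0, 0.9, 0, 0, 10, 10), det(1, 1, 0.9, 0, 0, 10, 10)]
        _, flags, fn = match_detections(dets, gts, 0.5)
        assert not flags.any() and fn == 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], [], 1.0)


class TestPrecisionRecall:
    def test_arithmetic(self):
        flags = np.array([True] * 9 + [False])
        p, r = precision_recall(flags, n_gt=10)
        assert (p, r) == (0.9, 0.9)

    def test_no_detections(self):
        assert precision_recall(np.array([], dtype=bool), 5) == (0.0, 0.0)

    def test_all_false_positives(self):
        p, _ = precision_recall(np.array([False, False]), 2)
        assert p == 0.0


class TestAveragePrecision:
    def test_perfect_ranking_is_one(self):
        assert average_precision(np.array([True, True]), 2) == 1.0

    def test_never_found_is_zero(self):
        assert average_precision(np.array([], dtype=bool), 1) == 0.0
        assert average_precision(np.array([False]), 1) == 0.0

    def test_small_case_against_oracle(self):
        flags = [True, False, True]
        got = average_precision(np.array(flags), 2)
        assert got == pytest.approx(reference_ap(flags, 2), abs=1e-12)
        assert got == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3), abs=1e-12)

    def test_random_flag_sequences_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            flags = list(rng.uniform(size=n) < 0.4)
            n_gt = max(sum(flags), int(rng.integers(1, 10)))
            assert average_precision(np.array(flags), n_gt) == pytest.approx(
                reference_ap(flags, n_gt), abs=1e-12
            )

    def test_confidence_rescaling_invariance(self):
        gts = [gt(0, 0, 0, 0, 10, 10), gt(0, 0, 30, 30, 40, 40)]
        dets = [det(0, 0, 0.8, 0, 0, 10, 10), det(0, 0, 0.4, 30, 30, 41, 41)]
        scaled = [
            Detection(d.image_id, d.class_id, d.confidence / 2, d.box) for d in dets
        ]
        a1 = evaluate(dets, gts).map50
        a2 = evaluate(scaled, gts).map50
        assert a1 == a2

    def test_duplicate_fp_never_increases_ap(self):
        gts = [gt(0, 0, 0, 0, 10, 10)]
        dets = [det(0, 0, 0.9, 0, 0, 10, 10)]
        base = evaluate(dets, gts).map50
        worse = evaluate(dets + [det(0, 0, 0.5, 50, 50, 60, 60)], gts).map50
        assert worse <= base


def _random_scene_records(rng, n_images=20, n_classes=3):
    gts, dets = [], []
    for img in range(n_images):
        for _ in range(rng.integers(1, 6)):
            cls = int(rng.integers(n_classes))
            x1, y1 = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 20, 2)
            g = gt(img, cls, x1, y1, x1 + w, y1 + h)
            gts.append(g)
            if rng.uniform() < 0.8:  # noisy matching detection
                dx, dy = rng.uniform(-3, 3, 2)
                dets.append(
                    det(
                        img,
                        cls if rng.uniform() < 0.9 else int(rng.integers(n_classes)),
                        float(rng.uniform(0.2, 1.0)),
                        x1 + dx,
                        y1 + dy,
                        x1 + w + dx,
                        y1 + h + dy,
                    )
                )
        for _ in range(rng.integers(0, 3)):  # pure false positives
            x1, y1 = rng.uniform(0, 80, 2)
            dets.append(
                det(img, int(rng.integers(n_classes)), float(rng.uniform(0.05, 0.9)),
                    x1, y1, x1 + 8, y1 + 8)
            )
    return dets, gts


def brute_force_map(dets, gts, iou_thr=0.5):
    """Fully independent reference mAP: per-class greedy matching + envelope AP."""
    classes = sorted({g.class_id for g in gts})
    aps = []
    for c in classes:
        c_dets = sorted(
            [d for d in dets if d.class_id == c], key=lambda d: -d.confidence
        )
        c_gts = [g for g in gts if g.class_id == c]
        used = set()
        flags = []
        for d in c_dets:
            best, best_i = 0.0, None
            for i, g in enumerate(c_gts):
                if i in used or g.image_id != d.image_id:
                    continue
                v = box_iou_xyxy(d.box, g.box)
                if v > best:
                    best, best_i = v, i
            if best_i is not None and best >= iou_thr:
                flags.append(True)
                used.add(best_i)
            else:
                flags.append(False)
        aps.append(reference_ap(flags, len(c_gts)))
    return float(np.mean(aps)) if aps else 0.0


class TestEvaluate:
    def test_perfect_single_class(self):
        gts = [gt(0, 0, 0, 0, 10, 10), gt(1, 0, 5, 5, 25, 25)]
        dets = [det(0, 0, 1.0, 0, 0, 10, 10), det(1, 0, 1.0, 5, 5, 25, 25)]
        s = evaluate(dets, gts)
        assert s.map50 == 1.0 and s.f1 == 1.0 and s.fn == 0

    def test_two_class_mean(self):
        gts = [gt(0, 0, 0, 0, 10, 10), gt(0, 1, 20, 20, 30, 30)]
        dets = [det(0, 0, 1.0, 0, 0, 10, 10)]  # class 1 never found
        s = evaluate(dets, gts)
        assert s.ap_per_class == {0: 1.0, 1: 0.0}
        assert s.map50 == 0.5

    def test_matches_brute_force_reference_on_random_scenes(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            dets, gts = _random_scene_records(rng)
            got = evaluate(dets, gts).map50
            want = brute_force_map(dets, gts)
            assert got == pytest.approx(want, abs=1e-9)

    def test_identity_detections_give_exact_map_one(self, small_scenes):
        from leafdet.infer import gts_from_scenes

        gts = gts_from_scenes(small_scenes)
        dets = [Detection(g.image_id, g.class_id, 1.0, g.box) for g in gts]
        assert evaluate(dets, gts).map50 == 1.0
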