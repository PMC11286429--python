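"""Tracking and counting metrics, cross-checked against an independent accumulator."""

from itertools import permutations

import numpy as np
import pytest

from peppertrack.geometry import BoundingBox, iou
from peppertrack.metrics import (
    EmptyGroundTruth,
    clear_mot_evaluate,
    count_unique_ids,
    counting_metrics,
    detection_pr,
    percent_reduction,
)
from peppertrack.postprocess import TrackSegment
from peppertrack.synthetic import ScenarioConfig, generate_scenario


def make_segment(seg_id, frames, x0=100.0, y0=100.0, vx=5.0, w=40.0, h=50.0):
    frames = list(frames)
    boxes = [BoundingBox(x0 + vx * (f - frames[0]), y0, w, h) for f in frames]
    feats = np.tile([1.0, 0.0], (len(frames), 1))
    return TrackSegment(id=seg_id, frames=frames, boxes=boxes, features=feats)


def reference_clear_mot(predicted, ground_truth, threshold=0.5):
    """Independent CLEAR accumulator using brute-force per-frame assignment.

    Same protocol, different machinery: matches maximize total overlap by
    enumerating permutations (scenes are kept small), pairings persist
    while valid, switches counted against the last known assignment.
    """
    pred_frames, gt_frames = {}, {}
    for seg in predicted:
        for f, b in zip(seg.frames, seg.boxes):
            pred_frames.setdefault(f, {})[seg.id] = b
    for seg in ground_truth:
        for f, b in zip(seg.frames, seg.boxes):
            gt_frames.setdefault(f, {})[seg.id] = b
    fp = fn = idsw = 0
    gt_total = sum(len(v) for v in gt_frames.values())
    overlaps = []
    last = {}
    prev = {}
    for f in sorted(set(pred_frames) | set(gt_frames)):
        gts = gt_frames.get(f, {})
        preds = pred_frames.get(f, {})
        pairs = {}
        for g, p in prev.items():
            if g in gts and p in preds and p not in pairs.values():
                if iou(gts[g], preds[p]) >= threshold:
                    pairs[g] = p
        free_g = [g for g in gts if g not in pairs]
        free_p = [p for p in preds if p not in pairs.values()]
        best, best_ov = {}, -1.0
        k = min(len(free_g), len(free_p))
        if k:
            for gsel in permutations(free_g, k):
                for psel in permutations(free_p, k):
                    cand = {
                        g: p for g, p in zip(gsel, psel) if iou(gts[g], preds[p]) >= threshold
                    }
                    total = sum(iou(gts[g], preds[p]) for g, p in cand.items())
                    if len(cand) > len(best) or (len(cand) == len(best) and total > best_ov):
                        best, best_ov = cand, total
        pairs.update(best)
        for g, p in pairs.items():
            if g in last and last[g] != p:
                idsw += 1
            last[g] = p
            overlaps.append(iou(gts[g], preds[p]))
        fn += len(gts) - len(pairs)
        fp += len(preds) - len(pairs)
        prev = pairs
    mota = (1 - (fp + fn + idsw) / gt_total) * 100
    motp = 100 * np.mean(overlaps) if overlaps else 0.0
    return dict(fp=fp, fn=fn, idsw=idsw, mota=mota, motp=motp)


class TestClearMot:
    def test_perfect_tracking(self):
        gt = [make_segment(1, range(1, 11)), make_segment(2, range(3, 9), y0=400)]
        rep = clear_mot_evaluate(gt, gt)
        assert (rep.fp, rep.fn, rep.idsw) == (0, 0, 0)
        assert rep.mota == pytest.approx(100.0)
        assert rep.motp == pytest.approx(100.0)

    def test_empty_predictions_all_missed(self):
        gt = [make_segment(1, range(1, 11))]
        rep = clear_mot_evaluate([], gt)
        assert rep.fn == rep.gt == 10
        assert rep.mota == pytest.approx(0.0)

    def test_identity_switch_counted_once(self):
        gt = [make_segment(1, range(1, 11))]
        pred = [make_segment(7, range(1, 6)), make_segment(8, range(6, 11), x0=100 + 5 * 5)]
        rep = clear_mot_evaluate(pred, gt)
        assert rep.idsw == 1
        assert (rep.fp, rep.fn) == (0, 0)

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(EmptyGroundTruth):
            clear_mot_evaluate([], [])

    def test_mota_decreases_with_errors(self):
        gt = [make_segment(1, range(1, 21))]
        clean = clear_mot_evaluate(gt, gt).mota
        noisy_pred = [make_segment(1, range(1, 16))]  # 5 misses
        assert clear_mot_evaluate(noisy_pred, gt).mota < clean

    def test_agrees_with_reference_on_synthetic_scenes(self):
        """Same FP/FN/IDSW/MOTA as the brute-force reference accumulator."""
        for seed in range(10):
            cfg = ScenarioConfig(
                n_frames=40, n_fruits=4, seed=seed, p_miss=0.15, fp_rate=0.3,
                n_occlusion_events=1, frame_width=700, frame_height=500,
                camera_speed=4.0,
            )
            scen = generate_scenario(cfg)
            # fabricate predictions: ground truth with per-seed id fragmentation
            preds = []
            next_id = 100
            for seg in scen.gt_segments:
                if len(seg) > 10 and seg.id % 2 == seed % 2:
                    cut = len(seg) // 2
                    preds.append(TrackSegment(next_id, seg.frames[:cut], seg.boxes[:cut], seg.features[:cut]))
                    preds.append(TrackSegment(next_id + 1, seg.frames[cut:], seg.boxes[cut:], seg.features[cut:]))
                    next_id += 2
                else:
                    preds.append(seg)
            got = clear_mot_evaluate(preds, scen.gt_segments)
            ref = reference_clear_mot(preds, scen.gt_segments)
            assert got.idsw == ref["idsw"]
            assert (got.fp, got.fn) == (ref["fp"], ref["fn"])
            assert got.mota == pytest.approx(ref["mota"], abs=1e-9)
            assert got.motp == pytest.approx(ref["motp"], abs=1e-9)


class TestCounting:
    @pytest.mark.parametrize(
        "pairs, acp, mae, rmse",
        [
            # fully improved tracker over the three survey videos
            ([(57, 62), (95, 96), (96, 100)], 95.34, 3.33, 3.74),
            # unmodified baseline
            ([(57, 63), (95, 104), (96, 111)], 88.13, 10.0, 10.68),
            # appearance re-matching only
            ([(57, 62), (95, 99), (96, 102)], 93.59, 5.0, 5.07),
            # track optimization only
            ([(57, 63), (95, 100), (96, 108)], 90.57, 7.67, 8.27),
            ([(10, 10), (20, 20)], 100.0, 0.0, 0.0),
        ],
    )
    def test_acp_mae_rmse(self, pairs, acp, mae, rmse):
        rep = counting_metrics(pairs)
        assert rep.acp == pytest.approx(acp, abs=0.011)
        assert rep.mae == pytest.approx(mae, abs=0.005)
        assert rep.rmse == pytest.approx(rmse, abs=0.005)

    @pytest.mark.parametrize(
        "gt, count, acp",
        [(95, 96, 98.95), (57, 62, 91.23), (96, 100, 95.83), (96, 111, 84.38)],
    )
    def test_single_video_precision(self, gt, count, acp):
        rep = counting_metrics([(gt, count)])
        assert rep.acp == pytest.approx(acp, abs=0.005)

    def test_gt_zero_rejected(self):
        with pytest.raises(ValueError):
            counting_metrics([(0, 5)])

    def test_count_unique_ids(self):
        assert count_unique_ids([]) == 0
        segs = [make_segment(i, range(1, 6)) for i in (4, 7, 9)]
        assert count_unique_ids(segs) == 3
        # after a merge mapping 7 -> 4
        segs = [make_segment(4, range(1, 6)), make_segment(9, range(1, 6), y0=300)]
        assert count_unique_ids(segs) == 2


class TestHelpers:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(68, 48, 29.41), (68, 51, 25.0), (68, 65, 4.41), (10, 10, 0.0)],
    )
    def test_percent_reduction(self, before, after, expected):
        assert percent_reduction(before, after) == pytest.approx(expected, abs=0.005)

    def test_percent_reduction_rejects_zero(self):
        with pytest.raises(ValueError):
            percent_reduction(0, 1)

    @pytest.mark.parametrize(
        "tp, fp, fn, p, r",
        [(90, 10, 0, 90.0, 100.0), (0, 0, 5, None, 0.0), (50, 50, 50, 50.0, 50.0)],
    )
    def test_detection_pr(self, tp, fp, fn, p, r):
        rep = detection_pr(tp, fp, fn)
        assert rep.precision == (pytest.approx(p) if p is not None else None)
        assert rep.recall == pytest.approx(r)
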