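"""Evaluation: CLEAR-MOT tracking metrics, counting metrics, detection utilities.

MOTA aggregates false positives, false negatives and identity switches
relative to the total number of ground-truth boxes:

    MOTA = (1 − (FP + FN + IDSW) / GT) × 100

MOTP here is the mean overlap (IOU) of matched prediction–truth pairs,
expressed in percent; a normalized-center-distance variant is available
through ``motp_mode``.  Matching follows the standard CLEAR protocol:
pairings persist from the previous frame while still valid, remaining
boxes are assigned by maximum overlap, and a ground-truth object whose
assigned prediction ID differs from its last known assignment counts one
identity switch.

Counting quality over a set of videos compares the true fruit count GT
with the tracker's unique-ID count:

    ACP  = 100 · mean(1 − |GT − COUNT| / GT)
    MAE  = mean |GT − COUNT|
    RMSE = sqrt(mean (GT − COUNT)²)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .association import solve_assignment
from .geometry import iou, normalized_center_distance
from .postprocess import TrackSegment


@dataclass
class MotReport:
    """CLEAR-MOT accumulation over one sequence."""

    fp: int
    fn: int
    idsw: int
    gt: int
    mota: float  # percent
    motp: float  # percent
    matched: int

    def format(self) -> str:
        return (
            f"GT boxes\t{self.gt}\nFP\t{self.fp}\nFN\t{self.fn}\nIDSW\t{self.idsw}\n"
            f"MOTA\t{self.mota:.1f}%\nMOTP\t{self.motp:.1f}%"
        )


@dataclass
class CountReport:
    """Per-video counts plus aggregate counting metrics."""

    pairs: list[tuple[int, int]]  # (GT, COUNT) per video
    acp: float  # percent
    mae: float  # fruits
    rmse: float  # fruits

    @property
    def n_videos(self) -> int:
        return len(self.pairs)

    def format(self) -> str:
        lines = ["Video\tGT\tCOUNT\tACP"]
        for i, (gt, count) in enumerate(self.pairs, start=1):
            lines.append(f"{i}\t{gt}\t{count}\t{100 * (1 - abs(gt - count) / gt):.2f}%")
        lines.append(f"overall\tACP {self.acp:.2f}%\tMAE {self.mae:.2f}\tRMSE {self.rmse:.2f}")
        return "\n".join(lines)


@dataclass
class DetReport:
    """Detection count arithmetic; rates are None when undefined."""

    tp: int
    fp: int
    fn: int
    precision: float | None  # percent
    recall: float | None  # percent


class EmptyGroundTruth(ValueError):
    """MOTA is undefined without ground-truth boxes."""


def _frame_index(segments: list[TrackSegment]) -> dict[int, dict[int, object]]:
    by_frame: dict[int, dict[int, object]] = {}
    for seg in segments:
        for frame, box in zip(seg.frames, seg.boxes):
            by_frame.setdefault(frame, {})[seg.id] = box
    return by_frame


def clear_mot_evaluate(
    predicted: list[TrackSegment],
    ground_truth: list[TrackSegment],
    iou_match_threshold: float = 0.5,
    motp_mode: str = "iou",
) -> MotReport:
    """Run the CLEAR-MOT accumulator over two sets of track segments."""
    if not ground_truth or sum(len(s) for s in ground_truth) == 0:
        raise EmptyGroundTruth("cannot evaluate MOTA with no ground-truth boxes")
    pred_by_frame = _frame_index(predicted)
    gt_by_frame = _frame_index(ground_truth)
    frames = sorted(set(pred_by_frame) | set(gt_by_frame))

    fp = fn = idsw = matched = 0
    gt_total = 0
    overlap_sum = 0.0
    dist_sum = 0.0
    current: dict[int, int] = {}  # gt id -> pred id active pairing
    last_seen: dict[int, int] = {}  # gt id -> last known pred id (across gaps)

    for frame in frames:
        gts = gt_by_frame.get(frame, {})
        preds = pred_by_frame.get(frame, {})
        gt_total += len(gts)
        used_preds: set[int] = set()
        pairs: list[tuple[int, int]] = []

        # 1. persist previous pairings that are still valid
        for gid, pid in list(current.items()):
            if gid in gts and pid in preds and pid not in used_preds:
                if iou(gts[gid], preds[pid]) >= iou_match_threshold:
                    pairs.append((gid, pid))
                    used_preds.add(pid)

        # 2. optimal overlap assignment of the remainder
        free_gids = [g for g in gts if g not in {p[0] for p in pairs}]
        free_pids = [p for p in preds if p not in used_preds]
        if free_gids and free_pids:
            cost = np.ones((len(free_gids), len(free_pids)))
            for i, g in enumerate(free_gids):
                for j, p in enumerate(free_pids):
                    ov = iou(gts[g], preds[p])
                    cost[i, j] = 1.0 - ov if ov >= iou_match_threshold else 1e5
            res = solve_assignment(cost, max_cost=1.0 - iou_match_threshold)
            for i, j in res.matches:
                pairs.append((free_gids[i], free_pids[j]))
                used_preds.add(free_pids[j])

        current = {}
        for gid, pid in pairs:
            if gid in last_seen and last_seen[gid] != pid:
                idsw += 1
            last_seen[gid] = pid
            current[gid] = pid
            matched += 1
            ov = iou(gts[gid], preds[pid])
            overlap_sum += ov
            dist_sum += normalized_center_distance(gts[gid], preds[pid])

        fn += len(gts) - len(pairs)
        fp += len(preds) - len(used_preds)

    mota = (1.0 - (fp + fn + idsw) / gt_total) * 100.0
    if matched == 0:
        motp = 0.0
    elif motp_mode == "iou":
        motp = 100.0 * overlap_sum / matched
    elif motp_mode == "norm_distance":
        motp = 100.0 * (1.0 - min(1.0, dist_sum / matched))
    else:
        raise ValueError(f"unknown motp_mode {motp_mode!r}")
    return MotReport(fp=fp, fn=fn, idsw=idsw, gt=gt_total, mota=mota, motp=motp, matched=matched)


def count_unique_ids(segments: list[TrackSegment]) -> int:
    """Number of distinct identities among finalized (or merged) segments."""
    return len({s.id for s in segments})


def counting_metrics(pairs: list[tuple[int, int]]) -> CountReport:
    """ACP / MAE / RMSE over per-video (true count, predicted count) pairs."""
    if not pairs:
        raise ValueError("need at least one (GT, COUNT) pair")
    if any(gt <= 0 for gt, _ in pairs):
        raise ValueError("every GT count must be positive")
    errors = [abs(gt - count) for gt, count in pairs]
    acp = 100.0 * sum(1.0 - e / gt for e, (gt, _) in zip(errors, pairs)) / len(pairs)
    mae = sum(errors) / len(pairs)
    rmse = math.sqrt(sum(e * e for e in errors) / len(pairs))
    return CountReport(pairs=list(pairs), acp=acp, mae=mae, rmse=rmse)


def percent_reduction(before: float, after: float) -> float:
    """Relative reduction in percent, e.g. 68 → 48 identity switches is 29.41%."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return 100.0 * (before - after) / before


def detection_pr(tp: int, fp: int, fn: int) -> DetReport:
    """Precision/recall count arithmetic; undefined ratios reported as None."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    return DetReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)
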