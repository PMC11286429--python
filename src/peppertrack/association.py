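"""Cost matrices, gating, optimal assignment, and cascade matching.

Association couples two complementary cues: appearance (cosine distance
between a detection's re-identification embedding and a track's feature
gallery) and motion (squared Mahalanobis distance of the detection from
the track's predicted box).  Appearance is the primary cost; motion acts
as a hard gate at the 0.95 chi-square quantile.  An IOU stage catches
tracks too young to carry a useful gallery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import BoundingBox, iou_matrix

#: Sentinel cost for pairs excluded from assignment.  Large but finite so
#: any solver can process the matrix; always demoted by max_cost.
INFEASIBLE = 1.0e5

#: 0.95 quantile of chi-square with 4 degrees of freedom — the default
#: Mahalanobis gate for a 4-dimensional box measurement.
CHI2_GATE_95 = 9.4877


@dataclass
class MatchResult:
    """Outcome of one assignment round.

    Every input index appears exactly once across ``matches`` and the
    unmatched lists.
    """

    matches: list[tuple[int, int]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)


def cosine_cost_matrix(
    track_galleries: list[np.ndarray], detection_features: np.ndarray
) -> np.ndarray:
    """Appearance cost: min over each track's gallery of 1 − cosine similarity.

    Embeddings are assumed unit-norm (ingest renormalizes).  Entries lie
    in [0, 2]; an empty gallery yields the infeasible sentinel.
    """
    n_det = len(detection_features)
    cost = np.full((len(track_galleries), n_det), INFEASIBLE, dtype=float)
    if n_det == 0:
        return cost
    feats = np.asarray(detection_features, dtype=float)
    for t, gallery in enumerate(track_galleries):
        if len(gallery) == 0:
            continue
        sims = np.asarray(gallery, dtype=float) @ feats.T  # (gallery, det)
        cost[t] = 1.0 - sims.max(axis=0)
    return cost


def iou_cost_matrix(
    track_boxes: list[BoundingBox], detection_boxes: list[BoundingBox]
) -> np.ndarray:
    """Overlap cost: 1 − IOU between predicted track boxes and detections."""
    return 1.0 - iou_matrix(track_boxes, detection_boxes)


def gate_cost_matrix(
    cost: np.ndarray, gating: np.ndarray, chi2_threshold: float = CHI2_GATE_95
) -> np.ndarray:
    """Mark entries whose squared Mahalanobis distance exceeds the gate infeasible."""
    cost = np.array(cost, dtype=float, copy=True)
    cost[np.asarray(gating) > chi2_threshold] = INFEASIBLE
    return cost


def solve_assignment(cost: np.ndarray, max_cost: float) -> MatchResult:
    """Minimum-cost one-to-one assignment with a per-pair acceptance threshold.

    Pairs whose optimal-assignment cost exceeds ``max_cost`` are demoted
    to unmatched.  Ties between equal-cost assignments are broken toward
    the lexicographically smallest (track, detection) pairing by a
    perturbation far below any meaningful cost difference.
    """
    cost = np.asarray(cost, dtype=float)
    n_tracks, n_dets = cost.shape
    if n_tracks == 0 or n_dets == 0:
        return MatchResult(
            matches=[],
            unmatched_tracks=list(range(n_tracks)),
            unmatched_detections=list(range(n_dets)),
        )
    # deterministic lexicographic tie-break
    tie = np.arange(n_tracks * n_dets, dtype=float).reshape(n_tracks, n_dets)
    eps = 1e-12 / max(n_tracks * n_dets, 1)
    rows, cols = linear_sum_assignment(cost + eps * tie)
    matches: list[tuple[int, int]] = []
    unmatched_tracks = set(range(n_tracks))
    unmatched_detections = set(range(n_dets))
    for r, c in zip(rows, cols):
        if cost[r, c] <= max_cost:
            matches.append((int(r), int(c)))
            unmatched_tracks.discard(int(r))
            unmatched_detections.discard(int(c))
    return MatchResult(
        matches=sorted(matches),
        unmatched_tracks=sorted(unmatched_tracks),
        unmatched_detections=sorted(unmatched_detections),
    )


def cascade_match(
    track_ages: list[int],
    cost_by_level: "CascadeCostFn",
    n_detections: int,
    max_age: int,
    max_cost: float,
) -> MatchResult:
    """Cascade over time-since-update levels, most recently seen tracks first.

    ``track_ages[i]`` is track i's frames-since-last-match (>= 1 after
    prediction).  ``cost_by_level(track_indices, detection_indices)``
    returns the gated cost sub-matrix for one level.  Each level solves
    an independent assignment over the detections still unmatched, so a
    recently updated track can never lose a detection to a long-lost one.
    """
    matches: list[tuple[int, int]] = []
    unmatched_detections = list(range(n_detections))
    unmatched_tracks: list[int] = []
    for age in range(1, max_age + 1):
        level_tracks = [i for i, a in enumerate(track_ages) if a == age]
        if not level_tracks:
            continue
        if not unmatched_detections:
            unmatched_tracks.extend(level_tracks)
            continue
        cost = cost_by_level(level_tracks, unmatched_detections)
        res = solve_assignment(cost, max_cost)
        for r, c in res.matches:
            matches.append((level_tracks[r], unmatched_detections[c]))
        unmatched_tracks.extend(level_tracks[r] for r in res.unmatched_tracks)
        unmatched_detections = [unmatched_detections[c] for c in res.unmatched_detections]
    # tracks older than max_age never entered any level
    leftover = [
        i for i, a in enumerate(track_ages) if a > max_age or a < 1
    ]
    unmatched_tracks.extend(leftover)
    return MatchResult(
        matches=sorted(matches),
        unmatched_tracks=sorted(unmatched_tracks),
        unmatched_detections=sorted(unmatched_detections),
    )


# typing helper for the cascade's per-level cost callback
from typing import Callable  # noqa: E402

CascadeCostFn = Callable[[list[int], list[int]], np.ndarray]
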