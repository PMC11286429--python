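"""Offline track optimization: stability filtering, pair voting, merging.

After the online tracker finishes, one fruit may be represented by
several track segments — either back-to-back identities from a continuous
ID switch, or fragments separated by an occlusion gap.  Both inflate the
unique-ID count.  This module repairs them in three steps:

1. **Stability filtering.**  A segment's per-frame appearance embeddings
   are compared with the segment's mean embedding; the variance of these
   cosine similarities, together with the segment length, classifies it
   as stable, partially stable, or unstable.  Unstable segments (short
   blips, incoherent appearance) are removed from counting; partially
   stable segments are counted but never merged.
2. **Similarity voting.**  For two temporally disjoint stable segments of
   M and N frames within a bounded gap, the M×N matrix of pairwise
   cosine similarities is computed; the pair is eligible when the number
   of entries at or above the vote threshold strictly exceeds M·N/2.
3. **Position and shape verification.**  Fruit in a constant-speed
   survey pass moves in uniform linear motion, so the earlier segment's
   mean velocity extrapolates its last box across the gap; the pair
   merges only if the extrapolated center lands within a tolerance of
   the later segment's first box (in mean-diagonal units) and the two
   boxes have compatible width/height ratios.

Merging is greedy over ascending temporal gap, interpolates the gap
linearly in tlwh space (flagged as interpolated), and iterates to a
fixpoint so chains of fragments collapse into one identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import RunConfig
from .geometry import BoundingBox, normalized_center_distance


@dataclass
class TrackSegment:
    """Finalized track: ordered frames, one box and one unit embedding per frame."""

    id: int
    frames: list[int]
    boxes: list[BoundingBox]
    features: np.ndarray  # (M, D), unit rows
    interpolated: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.frames)
        if m < 1 or len(self.boxes) != m or len(self.features) != m:
            raise ValueError("frames, boxes and features must have equal length >= 1")
        if any(b >= a for a, b in zip(self.frames[1:], self.frames)):
            raise ValueError("frames must be strictly increasing")
        feats = np.asarray(self.features, dtype=float)
        norms = np.linalg.norm(feats, axis=1, keepdims=True)
        self.features = feats / norms
        if not self.interpolated:
            self.interpolated = [False] * m

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start(self) -> int:
        return self.frames[0]

    @property
    def end(self) -> int:
        return self.frames[-1]

    @property
    def mean_feature(self) -> np.ndarray:
        m = self.features.mean(axis=0)
        return m / np.linalg.norm(m)


class StabilityLabel(Enum):
    STABLE = "stable"
    PARTIALLY_STABLE = "partially_stable"
    UNSTABLE = "unstable"


@dataclass
class StabilityVerdict:
    label: StabilityLabel
    length: int
    similarity_variance: float


def segment_stability(
    segment: TrackSegment,
    min_length: int = 5,
    var_partial: float = 0.01,
    var_max: float = 0.05,
) -> StabilityVerdict:
    """Classify a segment by length and appearance-similarity variance.

    unstable: shorter than ``min_length`` or variance above ``var_max``;
    partially stable: variance in (``var_partial``, ``var_max``];
    stable: otherwise.
    """
    sims = segment.features @ segment.mean_feature
    variance = float(np.var(sims))
    if len(segment) < min_length or variance > var_max:
        label = StabilityLabel.UNSTABLE
    elif variance > var_partial:
        label = StabilityLabel.PARTIALLY_STABLE
    else:
        label = StabilityLabel.STABLE
    return StabilityVerdict(label=label, length=len(segment), similarity_variance=variance)


@dataclass
class VoteOutcome:
    eligible: bool
    votes: int
    total: int  # M * N


def pair_similarity_vote(
    seg_a: TrackSegment,
    seg_b: TrackSegment,
    similarity_min: float = 0.8,
    max_gap: int = 45,
) -> VoteOutcome:
    """M×N appearance vote between two temporally disjoint segments.

    Segments are ordered so the earlier one comes first; pairs that
    overlap in time or whose gap (frames strictly between them) exceeds
    ``max_gap`` are ineligible.  Eligibility requires the vote count to
    *strictly* exceed half of M·N.
    """
    if seg_a.start > seg_b.start:
        seg_a, seg_b = seg_b, seg_a
    total = len(seg_a) * len(seg_b)
    if seg_b.start <= seg_a.end:  # temporal overlap
        return VoteOutcome(False, 0, total)
    gap = seg_b.start - seg_a.end - 1
    if gap > max_gap:
        return VoteOutcome(False, 0, total)
    sims = seg_a.features @ seg_b.features.T
    votes = int(np.count_nonzero(sims >= similarity_min))
    return VoteOutcome(votes > total / 2.0, votes, total)


def position_shape_match(
    seg_a: TrackSegment,
    seg_b: TrackSegment,
    max_center_dist: float = 1.0,
    max_shape_ratio: float = 1.5,
) -> bool:
    """Uniform-linear-motion position check plus box-shape compatibility.

    The earlier segment's mean per-frame center velocity extrapolates its
    last box to the later segment's first frame; position passes when the
    normalized center distance of that extrapolated box to the later
    segment's first box is within ``max_center_dist``.  Shape passes when
    the width and height ratios (larger over smaller) are both within
    ``max_shape_ratio``.
    """
    if seg_a.start > seg_b.start:
        seg_a, seg_b = seg_b, seg_a
    last = seg_a.boxes[-1]
    first = seg_b.boxes[0]
    if len(seg_a) > 1:
        (x0, y0) = seg_a.boxes[0].center
        (x1, y1) = last.center
        span = seg_a.end - seg_a.start
        vx, vy = (x1 - x0) / span, (y1 - y0) / span
    else:
        vx = vy = 0.0
    dt = seg_b.start - seg_a.end
    cx, cy = last.center
    extrapolated = BoundingBox(
        left=cx + vx * dt - last.width / 2.0,
        top=cy + vy * dt - last.height / 2.0,
        width=last.width,
        height=last.height,
    )
    if normalized_center_distance(extrapolated, first) > max_center_dist:
        return False
    wr = max(last.width, first.width) / min(last.width, first.width)
    hr = max(last.height, first.height) / min(last.height, first.height)
    return wr <= max_shape_ratio and hr <= max_shape_ratio


def _interpolate_gap(seg_a: TrackSegment, seg_b: TrackSegment) -> TrackSegment:
    """Join two disjoint segments, filling the gap linearly in tlwh space."""
    gap_frames = list(range(seg_a.end + 1, seg_b.start))
    frames = list(seg_a.frames)
    boxes = list(seg_a.boxes)
    interp = list(seg_a.interpolated)
    feats = [seg_a.features]
    if gap_frames:
        a = seg_a.boxes[-1].to_tlwh()
        b = seg_b.boxes[0].to_tlwh()
        fa = seg_a.features[-1]
        fb = seg_b.features[0]
        span = seg_b.start - seg_a.end
        gap_feats = []
        for f in gap_frames:
            w = (f - seg_a.end) / span
            tlwh = (1 - w) * a + w * b
            boxes.append(BoundingBox(*tlwh))
            frames.append(f)
            interp.append(True)
            gap_feats.append((1 - w) * fa + w * fb)
        feats.append(np.array(gap_feats))
    frames += list(seg_b.frames)
    boxes += list(seg_b.boxes)
    interp += list(seg_b.interpolated)
    feats.append(seg_b.features)
    return TrackSegment(
        id=seg_a.id,
        frames=frames,
        boxes=boxes,
        features=np.vstack(feats),
        interpolated=interp,
    )


@dataclass
class MergeReport:
    """Audit trail of one optimization pass."""

    dropped_unstable: list[int] = field(default_factory=list)
    pairs_considered: list[tuple[int, int, int, int, bool]] = field(default_factory=list)
    #: (earlier id, later id, votes, M*N, merged?)
    id_mapping: dict[int, int] = field(default_factory=dict)

    def format(self) -> str:
        lines = [f"dropped unstable segments: {self.dropped_unstable or 'none'}"]
        for a, b, votes, total, merged in self.pairs_considered:
            verdict = "MERGED" if merged else "rejected"
            lines.append(f"pair ({a}, {b}): votes {votes}/{total} -> {verdict}")
        for old, new in sorted(self.id_mapping.items()):
            lines.append(f"id {old} -> {new}")
        return "\n".join(lines)


def merge_segments(
    segments: list[TrackSegment], config: RunConfig | None = None
) -> tuple[list[TrackSegment], MergeReport]:
    """Full offline optimization: filter, vote, verify, merge to fixpoint.

    Returns the surviving segments (stable — possibly merged — plus
    partially stable) and a report carrying the old-id → new-id mapping
    and the audit trail.  Idempotent: a second pass changes nothing.
    """
    cfg = config or RunConfig()
    report = MergeReport()
    stable: list[TrackSegment] = []
    kept_partial: list[TrackSegment] = []
    for seg in segments:
        verdict = segment_stability(
            seg, cfg.stability_min_length, cfg.stability_var_partial, cfg.stability_var_max
        )
        if verdict.label is StabilityLabel.UNSTABLE:
            report.dropped_unstable.append(seg.id)
        elif verdict.label is StabilityLabel.PARTIALLY_STABLE:
            kept_partial.append(seg)
        else:
            stable.append(seg)

    mapping = {s.id: s.id for s in stable + kept_partial}

    while True:
        candidates = []
        for i in range(len(stable)):
            for j in range(len(stable)):
                if i == j:
                    continue
                a, b = stable[i], stable[j]
                if a.start > b.start or (a.start == b.start and a.id >= b.id):
                    continue
                vote = pair_similarity_vote(a, b, cfg.vote_similarity_min, cfg.merge_max_gap)
                if not vote.eligible:
                    continue
                shape_ok = position_shape_match(
                    a, b, cfg.merge_max_center_dist, cfg.merge_max_shape_ratio
                )
                report.pairs_considered.append((a.id, b.id, vote.votes, vote.total, shape_ok))
                if not shape_ok:
                    continue
                gap = b.start - a.end - 1
                sim = float(np.mean(a.features @ b.features.T))
                candidates.append((gap, -sim, a.id, b.id, i, j))
        if not candidates:
            break
        candidates.sort()
        _, _, _, _, i, j = candidates[0]
        a, b = stable[i], stable[j]
        merged = _interpolate_gap(a, b)
        for old, new in mapping.items():
            if new == b.id:
                mapping[old] = a.id
        stable = [s for k, s in enumerate(stable) if k not in (i, j)] + [merged]

    report.id_mapping = mapping
    out = sorted(stable + kept_partial, key=lambda s: (s.start, s.id))
    return out, report
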