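"""Online multi-object tracker: track lifecycle plus the improved matching flow.

Per frame, the pipeline runs four stages:

1. Kalman prediction for every live track.
2. Cascade matching of confirmed tracks against detections — cosine
   appearance cost, Mahalanobis-gated, most recently updated tracks first.
3. IOU matching for the leftovers that cannot carry appearance reliably:
   tentative tracks and confirmed tracks missed for exactly one frame.
4. Appearance re-matching: still-unmatched detections against confirmed
   tracks that lost their match this frame.  Pure cosine cost with a
   stricter threshold and *no* motion gate — this stage exists precisely
   because the motion state is assumed mutated (occlusion, camera shake,
   branch movement).  A re-matched track keeps its identity and gallery
   but re-initializes its Kalman state from the new detection.

Unmatched detections seed tentative tracks; a tentative track confirms
after ``n_init`` consecutive hits and dies on its first miss; a confirmed
track dies after ``max_age`` consecutive misses.  Counting by unique IDs
then only tallies tracks that ever confirmed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import association, kalman
from .config import RunConfig
from .geometry import BoundingBox, InvalidBoxError, tlwh_to_xyah, xyah_to_tlwh
from .postprocess import TrackSegment

logger = logging.getLogger(__name__)


@dataclass
class Detection:
    """One detector output: box, confidence, unit-norm appearance embedding."""

    frame: int
    box: BoundingBox
    confidence: float
    feature: np.ndarray

    def __post_init__(self) -> None:
        feat = np.asarray(self.feature, dtype=float)
        norm = np.linalg.norm(feat)
        if norm == 0:
            raise ValueError("appearance feature must be nonzero")
        self.feature = feat / norm


class TrackState(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class Track:
    """One identity: lifecycle state, motion state, feature gallery, history."""

    track_id: int
    state: TrackState
    kalman_state: kalman.KalmanState
    gallery: list[np.ndarray] = field(default_factory=list)
    hits: int = 1
    time_since_update: int = 0
    history: list[tuple[int, BoundingBox, np.ndarray]] = field(default_factory=list)
    ever_confirmed: bool = False

    def predicted_box(self) -> BoundingBox:
        return xyah_to_tlwh(self.kalman_state.mean[:4])


class Tracker:
    """Stateful per-frame tracker; feed frames in increasing order via :meth:`step`."""

    def __init__(self, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.model = kalman.KalmanModel()
        self.tracks: list[Track] = []
        self._finished: list[Track] = []
        self._next_id = 1
        self._last_frame = 0

    # ------------------------------------------------------------------ steps

    def step(self, frame: int, detections: list[Detection]) -> list[tuple[int, BoundingBox]]:
        """Process one frame; returns (track id, box) for confirmed tracks matched now."""
        if frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing: got {frame} after {self._last_frame}"
            )
        self._last_frame = frame
        detections = self._ingest(frame, detections)

        for track in self.tracks:
            track.kalman_state = kalman.predict(track.kalman_state, self.model)
            track.time_since_update += 1

        confirmed = [i for i, t in enumerate(self.tracks) if t.state is TrackState.CONFIRMED]
        other = [i for i, t in enumerate(self.tracks) if t.state is TrackState.TENTATIVE]

        matches, unmatched_confirmed, unmatched_dets = self._cascade_stage(
            confirmed, detections
        )

        iou_candidates = other + [
            i for i in unmatched_confirmed if self.tracks[i].time_since_update == 1
        ]
        lost_confirmed = [
            i for i in unmatched_confirmed if self.tracks[i].time_since_update > 1
        ]
        iou_matches, unmatched_iou_tracks, unmatched_dets = self._iou_stage(
            iou_candidates, detections, unmatched_dets
        )
        matches += iou_matches
        lost_confirmed += [
            i for i in unmatched_iou_tracks if self.tracks[i].state is TrackState.CONFIRMED
        ]
        unmatched_other = [
            i for i in unmatched_iou_tracks if self.tracks[i].state is TrackState.TENTATIVE
        ]

        rematches: list[tuple[int, int]] = []
        if self.config.enable_rematch and lost_confirmed and unmatched_dets:
            rematches, lost_confirmed, unmatched_dets = self._rematch_stage(
                lost_confirmed, detections, unmatched_dets
            )

        outputs: list[tuple[int, BoundingBox]] = []
        for ti, di in matches:
            self._update_track(self.tracks[ti], detections[di], frame)
        for ti, di in rematches:
            self._reattach_track(self.tracks[ti], detections[di], frame)
        for ti, di in matches + rematches:
            t = self.tracks[ti]
            if t.state is TrackState.CONFIRMED:
                outputs.append((t.track_id, detections[di].box))

        for ti in unmatched_other + lost_confirmed:
            self._mark_missed(self.tracks[ti])

        for di in unmatched_dets:
            self._initiate_track(detections[di], frame)

        live: list[Track] = []
        for t in self.tracks:
            if t.state is TrackState.DELETED:
                self._finished.append(t)
            else:
                live.append(t)
        self.tracks = live
        return sorted(outputs)

    def finalize(self) -> list[TrackSegment]:
        """Export every track that ever confirmed as an offline segment."""
        segments = []
        for t in self._finished + self.tracks:
            if not t.ever_confirmed or not t.history:
                continue
            frames = [f for f, _, _ in t.history]
            boxes = [b for _, b, _ in t.history]
            feats = np.array([v for _, _, v in t.history])
            segments.append(TrackSegment(id=t.track_id, frames=frames, boxes=boxes, features=feats))
        return sorted(segments, key=lambda s: s.id)

    # ----------------------------------------------------------------- stages

    def _cascade_stage(self, confirmed: list[int], detections: list[Detection]):
        if not confirmed or not detections:
            return [], list(confirmed), list(range(len(detections)))
        feats = np.array([d.feature for d in detections])
        xyah = np.array([tlwh_to_xyah(d.box) for d in detections])
        cfg = self.config

        def cost_fn(track_idx: list[int], det_idx: list[int]) -> np.ndarray:
            tracks = [self.tracks[confirmed[i]] for i in track_idx]
            galleries = [np.array(t.gallery) for t in tracks]
            cost = association.cosine_cost_matrix(galleries, feats[det_idx])
            gating = np.array(
                [
                    kalman.gating_distance(t.kalman_state, xyah[det_idx], self.model)
                    for t in tracks
                ]
            )
            if cfg.appearance_weight > 0:
                cost = (1 - cfg.appearance_weight) * cost + cfg.appearance_weight * gating
            return association.gate_cost_matrix(cost, gating, cfg.chi2_gate)

        ages = [self.tracks[i].time_since_update for i in confirmed]
        res = association.cascade_match(
            ages, cost_fn, len(detections), cfg.max_age, cfg.cascade_max_cost
        )
        matches = [(confirmed[t], d) for t, d in res.matches]
        unmatched_tracks = [confirmed[t] for t in res.unmatched_tracks]
        return matches, unmatched_tracks, res.unmatched_detections

    def _iou_stage(self, candidates: list[int], detections, unmatched_dets: list[int]):
        if not candidates or not unmatched_dets:
            return [], list(candidates), list(unmatched_dets)
        track_boxes = [self.tracks[i].predicted_box() for i in candidates]
        det_boxes = [detections[d].box for d in unmatched_dets]
        cost = association.iou_cost_matrix(track_boxes, det_boxes)
        res = association.solve_assignment(cost, self.config.iou_max_cost)
        matches = [(candidates[t], unmatched_dets[d]) for t, d in res.matches]
        unmatched_tracks = [candidates[t] for t in res.unmatched_tracks]
        unmatched = [unmatched_dets[d] for d in res.unmatched_detections]
        return matches, unmatched_tracks, unmatched

    def _rematch_stage(self, lost: list[int], detections, unmatched_dets: list[int]):
        """Appearance-only recovery of motion-orphaned confirmed tracks."""
        galleries = [np.array(self.tracks[i].gallery) for i in lost]
        feats = np.array([detections[d].feature for d in unmatched_dets])
        cost = association.cosine_cost_matrix(galleries, feats)
        res = association.solve_assignment(cost, self.config.rematch_max_cost)
        rematches = [(lost[t], unmatched_dets[d]) for t, d in res.matches]
        unmatched_tracks = [lost[t] for t in res.unmatched_tracks]
        unmatched = [unmatched_dets[d] for d in res.unmatched_detections]
        if rematches:
            logger.debug("appearance re-match recovered %d track(s)", len(rematches))
        return rematches, unmatched_tracks, unmatched

    # -------------------------------------------------------------- lifecycle

    def _ingest(self, frame: int, detections: list[Detection]) -> list[Detection]:
        kept = []
        for d in detections:
            if d.frame != frame:
                raise ValueError(f"detection frame {d.frame} != step frame {frame}")
            if d.confidence < self.config.min_confidence:
                continue
            kept.append(d)
        return kept

    def _update_track(self, track: Track, det: Detection, frame: int) -> None:
        measurement = tlwh_to_xyah(det.box)
        track.kalman_state, _ = kalman.update(track.kalman_state, measurement, self.model)
        self._register_hit(track, det, frame)

    def _reattach_track(self, track: Track, det: Detection, frame: int) -> None:
        # motion state is untrusted after a mutation: restart from the detection
        track.kalman_state = kalman.initiate(tlwh_to_xyah(det.box), self.model)
        self._register_hit(track, det, frame)

    def _register_hit(self, track: Track, det: Detection, frame: int) -> None:
        track.gallery.append(det.feature)
        if len(track.gallery) > self.config.gallery_budget:
            track.gallery = track.gallery[-self.config.gallery_budget :]
        track.hits += 1
        track.time_since_update = 0
        track.history.append((frame, det.box, det.feature))
        if track.state is TrackState.TENTATIVE and track.hits >= self.config.n_init:
            track.state = TrackState.CONFIRMED
            track.ever_confirmed = True

    def _mark_missed(self, track: Track) -> None:
        if track.state is TrackState.TENTATIVE:
            track.state = TrackState.DELETED
        elif track.time_since_update > self.config.max_age:
            track.state = TrackState.DELETED

    def _initiate_track(self, det: Detection, frame: int) -> None:
        state = kalman.initiate(tlwh_to_xyah(det.box), self.model)
        track = Track(
            track_id=self._next_id,
            state=TrackState.TENTATIVE,
            kalman_state=state,
            gallery=[det.feature],
            hits=1,
            time_since_update=0,
            history=[(frame, det.box, det.feature)],
        )
        if self.config.n_init <= 1:
            track.state = TrackState.CONFIRMED
            track.ever_confirmed = True
        self._next_id += 1
        self.tracks.append(track)


def make_detection(
    frame: int, tlwh: tuple[float, float, float, float], confidence: float, feature: np.ndarray
) -> Detection | None:
    """Build a Detection, dropping degenerate boxes with a warning."""
    try:
        box = BoundingBox(*tlwh)
    except InvalidBoxError:
        logger.warning("dropping degenerate detection box %s at frame %d", tlwh, frame)
        return None
    return Detection(frame=frame, box=box, confidence=confidence, feature=feature)


def run_tracker(
    frames: dict[int, list[Detection]], config: RunConfig | None = None
) -> list[TrackSegment]:
    """Convenience driver: run the tracker over a frame-indexed detection dict."""
    tracker = Tracker(config)
    for frame in sorted(frames):
        tracker.step(frame, frames[frame])
    return tracker.finalize()
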