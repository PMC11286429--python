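"""Offline track optimization: stability, voting, kinematics, merging."""

import numpy as np
import pytest

from peppertrack.config import RunConfig
from peppertrack.geometry import BoundingBox
from peppertrack.postprocess import (
    StabilityLabel,
    TrackSegment,
    merge_segments,
    pair_similarity_vote,
    position_shape_match,
    segment_stability,
)

from conftest import unit


def make_segment(seg_id, frames, x0=100.0, y0=100.0, vx=5.0, vy=0.0,
                 w=40.0, h=50.0, feature=(1.0, 0.0, 0.0), features=None):
    frames = list(frames)
    boxes = [BoundingBox(x0 + vx * (f - frames[0]), y0 + vy * (f - frames[0]), w, h) for f in frames]
    if features is None:
        features = np.tile(unit(feature), (len(frames), 1))
    return TrackSegment(id=seg_id, frames=frames, boxes=boxes, features=np.asarray(features, float))


class TestStability:
    def test_short_segment_unstable(self):
        seg = make_segment(1, [3])
        assert segment_stability(seg, min_length=5).label is StabilityLabel.UNSTABLE

    def test_identical_features_stable(self):
        seg = make_segment(1, range(1, 11))
        verdict = segment_stability(seg, min_length=5)
        assert verdict.label is StabilityLabel.STABLE
        assert verdict.similarity_variance == pytest.approx(0.0, abs=1e-15)

    def test_orthogonal_feature_flips_unstable(self):
        """An 8/2 split between orthogonal directions: similarities to the
        unit mean are 0.8/sqrt(0.68) and 0.2/sqrt(0.68), whose variance
        p·q·(a−b)² ≈ 0.0847 exceeds the 0.05 cap."""
        feats = [unit((1, 0, 0))] * 8 + [unit((0, 1, 0))] * 2
        seg = make_segment(1, range(1, 11), features=feats)
        verdict = segment_stability(seg, min_length=5, var_max=0.05)
        a, b = 0.8 / np.sqrt(0.68), 0.2 / np.sqrt(0.68)
        assert verdict.similarity_variance == pytest.approx(0.8 * 0.2 * (a - b) ** 2)
        assert verdict.label is StabilityLabel.UNSTABLE

    def test_partial_band(self):
        rng = np.random.default_rng(0)
        base = unit((1, 1, 0))
        feats = [unit(base + rng.normal(0, 0.35, 3)) for _ in range(12)]
        seg = make_segment(1, range(1, 13), features=feats)
        v = segment_stability(seg, min_length=5, var_partial=1e-6, var_max=1.0)
        assert v.label is StabilityLabel.PARTIALLY_STABLE


class TestVote:
    def test_unanimous_vote_eligible(self):
        a = make_segment(1, [1, 2])
        b = make_segment(2, [10, 11])
        out = pair_similarity_vote(a, b, similarity_min=0.8)
        assert (out.eligible, out.votes, out.total) == (True, 4, 4)

    def test_zero_similarity_ineligible(self):
        a = make_segment(1, [1, 2], feature=(1, 0, 0))
        b = make_segment(2, [10, 11], feature=(0, 1, 0))
        out = pair_similarity_vote(a, b, similarity_min=0.8)
        assert (out.eligible, out.votes) == (False, 0)

    def test_exact_half_votes_ineligible(self):
        """Votes must strictly exceed M*N/2."""
        a = make_segment(1, [1, 2])
        feats = [unit((1, 0, 0)), unit((0, 1, 0))]  # one matching, one orthogonal
        b = make_segment(2, [10, 11], features=feats)
        out = pair_similarity_vote(a, b, similarity_min=0.8)
        assert out.votes == out.total / 2
        assert not out.eligible

    def test_overlapping_segments_ineligible(self):
        a = make_segment(1, [1, 2, 3, 4])
        b = make_segment(2, [4, 5, 6])
        assert not pair_similarity_vote(a, b).eligible

    def test_gap_beyond_limit_ineligible(self):
        a = make_segment(1, [1, 2])
        b = make_segment(2, [60, 61])
        assert not pair_similarity_vote(a, b, max_gap=45).eligible
        assert pair_similarity_vote(a, b, max_gap=60).eligible

    def test_argument_order_irrelevant(self):
        a = make_segment(1, [1, 2])
        b = make_segment(2, [10, 11])
        assert pair_similarity_vote(b, a).eligible


class TestPositionShape:
    def test_exact_linear_extrapolation_passes(self):
        a = make_segment(1, range(1, 6), x0=100, vx=2.0)
        # segment a ends frame 5 at x=108; gap of 4, b starts frame 10 at x=118
        b = make_segment(2, range(10, 15), x0=100 + 2.0 * 9, vx=2.0)
        assert position_shape_match(a, b)

    def test_shape_ratio_rejects(self):
        a = make_segment(1, range(1, 6), w=40, h=50)
        b = make_segment(2, range(10, 15), x0=100 + 5.0 * 9, w=120, h=50)
        assert not position_shape_match(a, b, max_shape_ratio=1.5)

    def test_position_tolerance_rejects_far_restart(self):
        a = make_segment(1, range(1, 6), vx=2.0)
        b = make_segment(2, range(10, 15), x0=100 + 2.0 * 9 + 500.0, vx=2.0)
        assert not position_shape_match(a, b, max_center_dist=1.0)


class TestMerge:
    def test_no_eligible_pairs_identity(self):
        a = make_segment(1, range(1, 10), feature=(1, 0, 0))
        b = make_segment(2, range(20, 30), feature=(0, 1, 0))
        merged, report = merge_segments([a, b])
        assert {s.id for s in merged} == {1, 2}
        assert report.id_mapping == {1: 1, 2: 2}

    def test_occlusion_fragment_merges_two_to_one(self):
        """One fruit split by a 10-frame occlusion, same appearance: 2 in, 1 out."""
        a = make_segment(1, range(1, 11), x0=100, vx=3.0)
        b = make_segment(2, range(21, 31), x0=100 + 3.0 * 20, vx=3.0)
        merged, report = merge_segments([a, b])
        assert len(merged) == 1
        assert merged[0].id == 1
        assert report.id_mapping == {1: 1, 2: 1}
        # gap filled and flagged
        assert merged[0].frames == list(range(1, 31))
        gap_flags = [i for f, i in zip(merged[0].frames, merged[0].interpolated) if 11 <= f <= 20]
        assert all(gap_flags) and len(gap_flags) == 10

    def test_chain_of_three_collapses_to_one(self):
        a = make_segment(1, range(1, 11), x0=100, vx=3.0)
        b = make_segment(2, range(16, 26), x0=100 + 3.0 * 15, vx=3.0)
        c = make_segment(3, range(31, 41), x0=100 + 3.0 * 30, vx=3.0)
        merged, report = merge_segments([a, b, c])
        assert len(merged) == 1
        assert report.id_mapping == {1: 1, 2: 1, 3: 1}

    def test_merge_never_increases_ids_and_is_idempotent(self):
        segs = [
            make_segment(1, range(1, 11), x0=100, vx=3.0),
            make_segment(2, range(21, 31), x0=160, vx=3.0),
            make_segment(3, range(1, 15), x0=800, y0=600, feature=(0, 1, 0)),
        ]
        merged, _ = merge_segments(segs)
        assert len(merged) <= len(segs)
        again, report = merge_segments(merged)
        assert [(s.id, s.frames) for s in again] == [(s.id, s.frames) for s in merged]
        assert all(old == new for old, new in report.id_mapping.items())

    def test_unstable_segments_dropped_but_audited(self):
        blip = make_segment(9, [5, 6])  # below min length
        keep = make_segment(1, range(1, 11))
        merged, report = merge_segments([keep, blip])
        assert {s.id for s in merged} == {1}
        assert report.dropped_unstable == [9]

    def test_merged_frames_strictly_increasing(self):
        a = make_segment(1, range(1, 11), vx=3.0)
        b = make_segment(2, range(12, 21), x0=100 + 3.0 * 11, vx=3.0)
        merged, _ = merge_segments([a, b])
        f = merged[0].frames
        assert all(y > x for x, y in zip(f, f[1:]))
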