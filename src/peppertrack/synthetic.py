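"""Synthetic orchard-survey scenario generator.

Emulates the capture regime the tracker is designed for: a 1920×1080
camera carried past a crop row at constant speed (30 fps), so every
fruit crosses the frame in uniform linear motion.  Each fruit carries a
fixed unit appearance embedding (its "identity vector"); detections are
the ground-truth boxes with Gaussian position/size jitter, Bernoulli
dropout, false positives, and angular noise on the embedding.

Occlusion events model the two failure modes the tracker mitigates:
during an event a fruit's detections drop out and its embeddings are
corrupted, and the event may displace the subsequent trajectory (a
"motion jolt", standing in for camera shake or a branch pushing the
fruit) — without the jolt a constant-velocity filter would bridge any
pure detection gap and no identity switches would occur.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BoundingBox
from .postprocess import TrackSegment
from .tracker import Detection


@dataclass
class OcclusionEvent:
    """Interval during which one fruit is occluded.

    drop_prob: probability each in-event detection is suppressed.
    embed_noise_mult: multiplier on embedding noise for in-event detections.
    motion_jolt: (dx, dy) pixel offset applied to the trajectory from the
    end of the event onward — the motion-feature mutation.
    """

    fruit: int
    start: int
    end: int
    drop_prob: float = 1.0
    embed_noise_mult: float = 5.0
    motion_jolt: tuple[float, float] = (0.0, 0.0)


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic survey clip.

    camera_speed is the horizontal scene drift in px/frame induced by the
    constant-speed survey vehicle; per-fruit velocity is that drift plus
    a small random deviation.  p_miss is the baseline per-detection
    dropout probability; fp_rate the expected false positives per frame;
    embed_noise the angular scale of embedding corruption.  If
    occlusion_events is empty and n_occlusion_events > 0, events are
    drawn from the seeded generator inside each fruit's visible span.
    """

    n_frames: int = 150
    n_fruits: int = 12
    frame_width: int = 1920
    frame_height: int = 1080
    fps: int = 30
    camera_speed: float = 6.0
    fruit_size_min: float = 45.0
    fruit_size_max: float = 110.0
    jitter_pos: float = 2.0
    jitter_size: float = 0.03
    p_miss: float = 0.05
    fp_rate: float = 0.2
    embed_dim: int = 32
    embed_noise: float = 0.10
    occlusion_events: list[OcclusionEvent] = field(default_factory=list)
    n_occlusion_events: int = 0
    occlusion_duration: tuple[int, int] = (4, 10)
    occlusion_jolt_px: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_miss",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_frames < 1 or self.n_fruits < 1:
            raise ValueError("n_frames and n_fruits must be >= 1")
        if self.fruit_size_min <= 0 or self.fruit_size_max < self.fruit_size_min:
            raise ValueError("invalid fruit size range")


@dataclass
class Scenario:
    """Generated clip: noise-free truth plus noisy detections.

    labels mirrors detections: the true fruit id behind each detection,
    or −1 for a false positive.  Diagnostics only — the tracker never
    sees them.
    """

    config: ScenarioConfig
    gt_segments: list[TrackSegment]
    detections: dict[int, list[Detection]]
    true_count: int
    labels: dict[int, list[int]] = field(default_factory=dict)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Simulate one clip; fully determined by ``config`` (including its seed)."""
    rng = np.random.default_rng(config.seed)
    cfg = config
    world_span = cfg.frame_width + cfg.camera_speed * cfg.n_frames

    # --- fruit geometry and kinematics -------------------------------------
    widths = rng.uniform(cfg.fruit_size_min, cfg.fruit_size_max, cfg.n_fruits)
    aspects = rng.uniform(0.7, 1.3, cfg.n_fruits)
    heights = widths / aspects
    world_x = rng.uniform(0.0, world_span - cfg.fruit_size_max, cfg.n_fruits)
    ys = rng.uniform(0.0, cfg.frame_height - heights)
    vx = -cfg.camera_speed * (1.0 + rng.normal(0.0, 0.02, cfg.n_fruits))
    vy = rng.normal(0.0, 0.05, cfg.n_fruits)
    identities = np.array([_unit(rng.normal(size=cfg.embed_dim)) for _ in range(cfg.n_fruits)])

    def raw_position(i: int, t: int) -> tuple[float, float]:
        # t is the 1-based frame index; the scene scrolls left as the car moves
        return world_x[i] + vx[i] * (t - 1), ys[i] + vy[i] * (t - 1)

    # visibility from the un-jolted trajectory
    visible: list[list[int]] = []
    for i in range(cfg.n_fruits):
        frames = []
        for t in range(1, cfg.n_frames + 1):
            x, y = raw_position(i, t)
            if -widths[i] * 0.25 <= x and x + widths[i] <= cfg.frame_width + widths[i] * 0.25:
                frames.append(t)
        visible.append(frames)

    # --- occlusion events ---------------------------------------------------
    events = list(cfg.occlusion_events)
    if not events and cfg.n_occlusion_events > 0:
        eligible = [i for i in range(cfg.n_fruits) if len(visible[i]) >= 30]
        chosen = rng.choice(
            eligible, size=min(cfg.n_occlusion_events, len(eligible)), replace=False
        )
        for i in sorted(int(c) for c in chosen):
            span = visible[i]
            dur = int(rng.integers(cfg.occlusion_duration[0], cfg.occlusion_duration[1] + 1))
            lo = span[len(span) // 4]
            hi = span[3 * len(span) // 4]
            start = int(rng.integers(lo, max(lo + 1, hi - dur)))
            angle = rng.uniform(0, 2 * np.pi)
            mag = cfg.occlusion_jolt_px * rng.uniform(0.7, 1.3)
            events.append(
                OcclusionEvent(
                    fruit=i,
                    start=start,
                    end=start + dur,
                    drop_prob=1.0,
                    embed_noise_mult=5.0,
                    motion_jolt=(mag * np.cos(angle), mag * np.sin(angle)),
                )
            )

    events_by_fruit: dict[int, list[OcclusionEvent]] = {}
    for ev in events:
        events_by_fruit.setdefault(ev.fruit, []).append(ev)

    def jolt_offset(i: int, t: int) -> tuple[float, float]:
        dx = dy = 0.0
        for ev in events_by_fruit.get(i, []):
            if t > ev.end:
                dx += ev.motion_jolt[0]
                dy += ev.motion_jolt[1]
        return dx, dy

    def box_at(i: int, t: int) -> BoundingBox:
        x, y = raw_position(i, t)
        dx, dy = jolt_offset(i, t)
        return BoundingBox(left=x + dx, top=y + dy, width=widths[i], height=heights[i])

    # --- ground truth -------------------------------------------------------
    gt_segments = []
    for i in range(cfg.n_fruits):
        if not visible[i]:
            continue
        frames = visible[i]
        boxes = [box_at(i, t) for t in frames]
        feats = np.tile(identities[i], (len(frames), 1))
        gt_segments.append(TrackSegment(id=i + 1, frames=frames, boxes=boxes, features=feats))
    true_count = len(gt_segments)

    # --- detections ---------------------------------------------------------
    detections: dict[int, list[Detection]] = {t: [] for t in range(1, cfg.n_frames + 1)}
    labels: dict[int, list[int]] = {t: [] for t in range(1, cfg.n_frames + 1)}
    for i in range(cfg.n_fruits):
        for t in visible[i]:
            noise_mult = 1.0
            dropped = rng.random() < cfg.p_miss
            for ev in events_by_fruit.get(i, []):
                if ev.start <= t <= ev.end:
                    noise_mult = max(noise_mult, ev.embed_noise_mult)
                    if rng.random() < ev.drop_prob:
                        dropped = True
            if dropped:
                continue
            box = box_at(i, t)
            w = max(1.0, box.width * (1.0 + rng.normal(0.0, cfg.jitter_size)))
            h = max(1.0, box.height * (1.0 + rng.normal(0.0, cfg.jitter_size)))
            jbox = BoundingBox(
                left=box.left + rng.normal(0.0, cfg.jitter_pos),
                top=box.top + rng.normal(0.0, cfg.jitter_pos),
                width=w,
                height=h,
            )
            scale = cfg.embed_noise * noise_mult
            feat = identities[i] + scale * rng.normal(size=cfg.embed_dim)
            conf = float(np.clip(rng.normal(0.85, 0.07), 0.31, 1.0))
            detections[t].append(Detection(frame=t, box=jbox, confidence=conf, feature=feat))
            labels[t].append(i + 1)
    for t in range(1, cfg.n_frames + 1):
        for _ in range(rng.poisson(cfg.fp_rate)):
            w = rng.uniform(cfg.fruit_size_min, cfg.fruit_size_max)
            h = w / rng.uniform(0.7, 1.3)
            fbox = BoundingBox(
                left=rng.uniform(0, cfg.frame_width - w),
                top=rng.uniform(0, cfg.frame_height - h),
                width=w,
                height=h,
            )
            feat = rng.normal(size=cfg.embed_dim)
            conf = float(np.clip(rng.normal(0.5, 0.1), 0.31, 1.0))
            detections[t].append(Detection(frame=t, box=fbox, confidence=conf, feature=feat))
            labels[t].append(-1)

    return Scenario(
        config=cfg,
        gt_segments=gt_segments,
        detections=detections,
        true_count=true_count,
        labels=labels,
    )


# --------------------------------------------------------------------- presets

#: True fruit counts and clip lengths for the three survey conditions
#: (low density / medium light, high density / medium light,
#: high density / low light); lengths follow the 12 s / 17 s / 20 s test
#: clips at 30 fps.  Density raises dropout; low light raises both
#: dropout and embedding noise.
_PRESETS: dict[str, dict] = {
    "low_density_medium_light": dict(
        n_fruits=57, n_frames=360, p_miss=0.06, embed_noise=0.10,
        fp_rate=0.2, n_occlusion_events=8,
    ),
    "high_density_medium_light": dict(
        n_fruits=95, n_frames=510, p_miss=0.10, embed_noise=0.12,
        fp_rate=0.4, n_occlusion_events=16,
    ),
    "high_density_low_light": dict(
        n_fruits=96, n_frames=600, p_miss=0.14, embed_noise=0.18,
        fp_rate=0.5, n_occlusion_events=20,
    ),
}

#: Number of scenarios in the occlusion suite.
OCCLUSION_SUITE_SIZE = 20


def preset(name: str, seed: int = 0):
    """Named study conditions.

    The three survey presets return one :class:`ScenarioConfig`;
    ``occlusion_suite`` returns a list of ``OCCLUSION_SUITE_SIZE``
    configs engineered to provoke both identity-switch modes (permanent
    and reversible) via occlusion gaps with motion jolts.
    """
    if name == "occlusion_suite":
        return occlusion_suite(seed)
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(_PRESETS)} + ['occlusion_suite']")
    return ScenarioConfig(seed=seed, **_PRESETS[name])


def occlusion_suite(seed: int = 0) -> list[ScenarioConfig]:
    """Twenty seeded occlusion-heavy scenarios for ablation studies."""
    base = ScenarioConfig(
        n_frames=150,
        n_fruits=12,
        p_miss=0.04,
        fp_rate=0.2,
        embed_noise=0.08,
        n_occlusion_events=6,
        occlusion_duration=(4, 10),
        occlusion_jolt_px=45.0,
    )
    return [replace(base, seed=seed + 1000 + k) for k in range(OCCLUSION_SUITE_SIZE)]
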