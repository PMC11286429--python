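"""Run configuration: every tunable of the pipeline with documented defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any


@dataclass
class RunConfig:
    """All pipeline tunables.  Unknown keys are rejected on load.

    Online tracker
    --------------
    min_confidence : drop detections below this score at ingest.
    n_init         : consecutive hits before a tentative track is confirmed.
    max_age        : frames a confirmed track survives without a match.
    gallery_budget : max embeddings retained per track (oldest evicted).
    cascade_max_cost : cosine-distance acceptance threshold in cascade matching.
    chi2_gate      : squared-Mahalanobis gate (0.95 chi-square, 4 dof).
    iou_max_cost   : 1 − IOU acceptance threshold of the overlap stage.
    rematch_max_cost : stricter cosine threshold of the appearance re-matching
                       stage for motion-orphaned tracks.
    appearance_weight : blend of motion distance into the cascade cost
                       (0 = pure appearance cost with motion used only as gate).
    enable_rematch : toggle the appearance re-matching stage.

    Offline track optimization
    --------------------------
    stability_min_length : segments shorter than this are unstable.
    stability_var_partial / stability_var_max : appearance-similarity variance
                       bands separating stable / partially stable / unstable.
    vote_similarity_min : cosine similarity counted as a vote in the M×N rule.
    merge_max_gap  : largest temporal gap (frames) bridgeable by a merge.
    merge_max_center_dist : position tolerance in mean-diagonal units.
    merge_max_shape_ratio : largest allowed width or height ratio.
    enable_postprocess : toggle offline merging.

    Evaluation
    ----------
    eval_iou_threshold : minimum overlap for a GT-prediction match.
    motp_mode      : "iou" (mean overlap × 100) or "norm_distance".

    seed : master seed for any randomized component.
    """

    min_confidence: float = 0.3
    n_init: int = 3
    max_age: int = 30
    gallery_budget: int = 100
    cascade_max_cost: float = 0.2
    chi2_gate: float = 9.4877
    iou_max_cost: float = 0.7
    rematch_max_cost: float = 0.15
    appearance_weight: float = 0.0
    enable_rematch: bool = True

    stability_min_length: int = 5
    stability_var_partial: float = 0.01
    stability_var_max: float = 0.05
    vote_similarity_min: float = 0.8
    merge_max_gap: int = 45
    merge_max_center_dist: float = 1.0
    merge_max_shape_ratio: float = 1.5
    enable_postprocess: bool = True

    eval_iou_threshold: float = 0.5
    motp_mode: str = "iou"

    seed: int = 0

    def __post_init__(self) -> None:
        if self.motp_mode not in ("iou", "norm_distance"):
            raise ValueError(f"motp_mode must be 'iou' or 'norm_distance', got {self.motp_mode!r}")
        for name in ("min_confidence",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_init", "max_age", "gallery_budget", "stability_min_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.stability_var_partial > self.stability_var_max:
            raise ValueError("stability_var_partial must not exceed stability_var_max")

    @classmethod
    def from_dict(cls, overrides: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
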