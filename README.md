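# peppertrack

Multi-object tracking and counting of fruit in orchard survey video.

Yield estimation by video survey works by detecting fruit in every frame,
linking the detections into per-fruit tracks, and counting the distinct
track identities: each fruit should contribute exactly one ID.  The hard
part is keeping identities stable.  Dense foliage and camera motion hide
fruit for a handful of frames and displace it off its predicted course,
and every such *identity switch* inflates the count — the same fruit is
tallied twice.

`peppertrack` implements a tracking-by-detection pipeline built for this
failure mode:

- **Constant-velocity Kalman filter** per track over the state
  (cx, cy, a, h, ẋ, ẏ, ȧ, ḣ) — box center, aspect ratio and height with
  per-frame velocities — with the standard recursion
  x̂ₜ = F xₜ₋₁, Pₜ|ₜ₋₁ = F P Fᵀ + Q, K = P Hᵀ (H P Hᵀ + R)⁻¹.
- **Cascade matching**: appearance cost (minimum cosine distance between
  a detection's re-identification embedding and the track's feature
  gallery) gated by the squared Mahalanobis distance at the χ²₀.₉₅(4)
  quantile, solved per time-since-update level by the Hungarian
  algorithm, plus an IOU stage for young tracks.
- **Appearance re-matching**: a recovery stage for tracks orphaned by
  *motion-feature mutations*.  Detections that no track claimed are
  matched against recently lost confirmed tracks by appearance alone —
  no motion gate, stricter cosine threshold — and a re-matched track
  keeps its identity while restarting its motion state.
- **Offline track optimization**: unstable segments are removed by the
  variance of their appearance self-similarity; for each temporally
  disjoint pair of stable segments an M×N cosine-similarity vote is
  taken (merge candidates need a strict majority), then the earlier
  segment's uniform linear motion is extrapolated across the gap and the
  pair merges only if position and box shape agree.  Merging interpolates
  the gap and iterates to a fixpoint.
- **Evaluation**: CLEAR-MOT (MOTA, MOTP, identity switches) and counting
  metrics over videos — ACP = 100·mean(1 − |GT−COUNT|/GT), MAE, RMSE.
- **Synthetic orchard simulator**: seeded scenarios reproducing the
  survey regime (1920×1080 at 30 fps, constant camera speed, fruit in
  uniform linear motion) with detection dropout, box jitter, embedding
  noise, false positives, and occlusion events that corrupt both
  appearance and motion.

## Worked example

```python
from peppertrack import (RunConfig, clear_mot_evaluate, count_unique_ids,
                         generate_scenario, merge_segments, preset, run_tracker)

scenario = generate_scenario(preset("low_density_medium_light", seed=1))
segments = run_tracker(scenario.detections, RunConfig())
merged, _ = merge_segments(segments, RunConfig())
mot = clear_mot_evaluate(merged, scenario.gt_segments)
print(scenario.true_count, count_unique_ids(merged), mot.mota, mot.idsw)
```

Output:

```
true fruit count : 57
unique-ID count  : 57
MOTA 93.1%  MOTP 90.1%  IDSW 0
```

57 of 57 fruits received exactly one identity (no double counting); MOTA
of 93.1% reflects the simulator's detection dropout and false positives,
and zero identity switches means no fruit changed ID mid-clip.  The
scripts in `examples/` walk through each capability — tracking a clip,
recovering a motion mutation, merging a fragmented track, the 2×2
ablation grid, and counting reports — and print the numbers they
compute.

## Command line

```bash
peppertrack simulate --preset high_density_low_light --seed 7 --out data/
peppertrack track --det data/det.txt --emb data/det_emb.txt --out pred.txt
peppertrack eval --pred pred.txt --gt data/gt.txt
peppertrack count --pred pred.txt --gt-counts 96
peppertrack ablate --seed 0
```

`track` accepts `--no-rematch` / `--no-postprocess` to ablate the two
improvements.  Files use the comma-separated MOT16 dialect
(`frame,id,left,top,w,h,conf,x,y,z`); embeddings ride in a sidecar
matrix with one row per detection line.

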