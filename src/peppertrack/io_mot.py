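"""MOT-Challenge text I/O plus the embedding sidecar and YAML run config.

File dialect: the 10-column comma-separated MOT16 layout
``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z`` with frame
indices 1-based and coordinates written to two decimals.  Raw detections
carry id −1.  Appearance embeddings travel in a separate
whitespace-delimited numeric matrix with exactly one row per detection
line, in the same order, since no MOT dialect carries features.  When
the sidecar is absent, a deterministic embedding is derived from the box
geometry so the pipeline can run in IOU-only fashion.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig
from .geometry import BoundingBox, InvalidBoxError
from .postprocess import TrackSegment
from .tracker import Detection

logger = logging.getLogger(__name__)

MOT_COLUMNS = ["frame", "id", "bb_left", "bb_top", "bb_width", "bb_height", "conf", "x", "y", "z"]


class MotFormatError(ValueError):
    """Malformed MOT file or mismatched embedding sidecar."""


def _hash_embedding(tlwh: tuple[float, float, float, float], dim: int = 32) -> np.ndarray:
    """Deterministic pseudo-embedding from box geometry (sidecar-less fallback)."""
    h = abs(hash(tuple(round(v, 2) for v in tlwh))) % (2**31)
    rng = np.random.default_rng(h)
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


def read_mot_file(path: str | Path) -> pd.DataFrame:
    """Parse a MOT text file into a DataFrame with MOT_COLUMNS."""
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=MOT_COLUMNS)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:
        raise MotFormatError(f"{path}: cannot parse as comma-separated MOT file: {exc}") from exc
    if df.shape[1] < 7:
        raise MotFormatError(f"{path}: expected >= 7 columns, found {df.shape[1]}")
    for col in range(df.shape[1], 10):
        df[col] = -1.0
    df = df.iloc[:, :10]
    df.columns = MOT_COLUMNS
    geom = df[["frame", "bb_left", "bb_top", "bb_width", "bb_height", "conf"]]
    numeric = geom.apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1)
    if bad_rows.any():
        bad = int(bad_rows.idxmax()) + 1
        raise MotFormatError(f"{path}: malformed line {bad}")
    df[numeric.columns] = numeric
    df["frame"] = df["frame"].astype(int)
    df["id"] = df["id"].astype(int)
    return df


def read_detections(
    det_path: str | Path,
    sidecar_path: str | Path | None = None,
    min_confidence: float = 0.0,
) -> dict[int, list[Detection]]:
    """Read a detection file (id column ignored) and attach embeddings.

    Detections are grouped by frame and embeddings renormalized.  A row
    count mismatch between file and sidecar is a hard error.  Degenerate
    boxes are dropped with a warning.
    """
    df = read_mot_file(det_path)
    if sidecar_path is not None:
        emb = np.atleast_2d(np.loadtxt(sidecar_path, ndmin=2))
        if emb.shape[0] != len(df):
            raise MotFormatError(
                f"embedding sidecar has {emb.shape[0]} rows for {len(df)} detection lines"
            )
    else:
        emb = None
    out: dict[int, list[Detection]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        tlwh = (row.bb_left, row.bb_top, row.bb_width, row.bb_height)
        try:
            box = BoundingBox(*tlwh)
        except InvalidBoxError:
            logger.warning("dropping degenerate detection %s at frame %d", tlwh, row.frame)
            continue
        if row.conf < min_confidence:
            continue
        feature = emb[i] if emb is not None else _hash_embedding(tlwh)
        out.setdefault(int(row.frame), []).append(
            Detection(frame=int(row.frame), box=box, confidence=float(row.conf), feature=feature)
        )
    return dict(sorted(out.items()))


def segments_to_mot(segments: list[TrackSegment]) -> pd.DataFrame:
    rows = []
    for seg in segments:
        for frame, box, interp in zip(seg.frames, seg.boxes, seg.interpolated):
            rows.append(
                (frame, seg.id, box.left, box.top, box.width, box.height, 1.0,
                 1 if interp else -1, -1, -1)
            )
    df = pd.DataFrame(rows, columns=MOT_COLUMNS)
    return df.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)


def write_tracks(segments: list[TrackSegment], path: str | Path) -> None:
    """Write finalized segments as MOT lines sorted by (frame, id).

    Interpolated frames are marked by 1 in the first placeholder column.
    """
    df = segments_to_mot(segments)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{int(row.frame)},{int(row.id)},{row.bb_left:.2f},{row.bb_top:.2f},"
                f"{row.bb_width:.2f},{row.bb_height:.2f},{row.conf:.2f},"
                f"{int(row.x)},{int(row.y)},{int(row.z)}\n"
            )


def write_detections(
    detections: dict[int, list[Detection]],
    det_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write per-frame detections (id −1) and optionally their embeddings."""
    features = []
    with open(det_path, "w") as fh:
        for frame in sorted(detections):
            for d in detections[frame]:
                b = d.box
                fh.write(
                    f"{frame},-1,{b.left:.2f},{b.top:.2f},{b.width:.2f},{b.height:.2f},"
                    f"{d.confidence:.2f},-1,-1,-1\n"
                )
                features.append(d.feature)
    if sidecar_path is not None:
        np.savetxt(sidecar_path, np.array(features), fmt="%.6f")


def read_tracks(path: str | Path, sidecar_path: str | Path | None = None) -> list[TrackSegment]:
    """Read a track file (gt or predictions) into segments grouped by id."""
    df = read_mot_file(path)
    if sidecar_path is not None:
        emb = np.atleast_2d(np.loadtxt(sidecar_path, ndmin=2))
        if emb.shape[0] != len(df):
            raise MotFormatError(
                f"embedding sidecar has {emb.shape[0]} rows for {len(df)} track lines"
            )
    else:
        emb = None
    segments = []
    df = df.sort_values(["id", "frame"], kind="stable")
    for track_id, group in df.groupby("id", sort=True):
        frames = group["frame"].tolist()
        boxes = [
            BoundingBox(r.bb_left, r.bb_top, r.bb_width, r.bb_height)
            for r in group.itertuples(index=False)
        ]
        if emb is not None:
            feats = emb[group.index.to_numpy()]
        else:
            feats = np.array(
                [_hash_embedding((b.left, b.top, b.width, b.height)) for b in boxes]
            )
        interp = [r.x == 1 for r in group.itertuples(index=False)]
        segments.append(
            TrackSegment(
                id=int(track_id), frames=frames, boxes=boxes, features=feats, interpolated=interp
            )
        )
    return segments


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Resolve the run configuration: defaults ← YAML file ← keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update(overrides)
    cfg = RunConfig.from_dict(data)
    logger.info("resolved config: %s", cfg.to_dict())
    return cfg
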