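"""Frame-sequence detection and per-identity trajectory assembly.

Every frame is decoded independently — no information flows between frames,
so a corrupted or missing frame affects only its own points and identity
errors cannot propagate along a trajectory.  Identity comes exclusively
from decoding; there is no smoothing, interpolation or re-identification
across gaps.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .codebook import Codebook
from .detector import DetectorOptions, locate_codes

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["id", "frame", "time_s", "x", "y", "orientation_deg",
                     "margin"]


def track_frames(frames,
                 options: DetectorOptions | None = None,
                 codebook: Codebook | None = None,
                 interval_s: float = 1.0,
                 timestamps=None) -> tuple[pd.DataFrame, list[int]]:
    """Run detection over an ordered frame sequence.

    ``frames`` is an iterable of images (arrays or paths).  Timestamps are
    ``frame_index * interval_s`` unless explicit ``timestamps`` are given.
    Returns (detections table, skipped frame indices); unreadable frames
    are logged and skipped, never fatal.
    """
    rows = []
    skipped: list[int] = []
    times = None if timestamps is None else list(timestamps)
    for idx, frame in enumerate(frames):
        t = times[idx] if times is not None else idx * interval_s
        try:
            if isinstance(frame, (str, Path)):
                frame = iio.imread(frame)
            dets = locate_codes(frame, options, codebook, frame_index=idx)
        except Exception as exc:  # unreadable frame: record and move on
            log.warning("frame %d skipped: %s", idx, exc)
            skipped.append(idx)
            continue
        for d in dets:
            rows.append({"id": d.id, "frame": idx, "time_s": t,
                         "x": d.centroid[0], "y": d.centroid[1],
                         "orientation_deg": d.orientation_deg,
                         "margin": d.margin})
    table = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    return table, skipped


@dataclass
class TrajectorySet:
    """Per-identity trajectories with frame metadata."""
    trajectories: dict[int, pd.DataFrame]
    n_frames: int = 0
    interval_s: float = 1.0
    duplicate_conflicts: int = 0

    @property
    def ids(self) -> list[int]:
        return sorted(self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __getitem__(self, tag_id: int) -> pd.DataFrame:
        return self.trajectories[int(tag_id)]

    @property
    def total_points(self) -> int:
        return sum(len(t) for t in self.trajectories.values())

    def to_table(self) -> pd.DataFrame:
        """Flat CSV layout: id, frame, time_s, x, y, orientation_deg."""
        if not self.trajectories:
            return pd.DataFrame(columns=["id", "frame", "time_s", "x", "y",
                                         "orientation_deg"])
        parts = [t.assign(id=i) for i, t in sorted(self.trajectories.items())]
        return pd.concat(parts, ignore_index=True)[
            ["id", "frame", "time_s", "x", "y", "orientation_deg"]]


def assemble_trajectories(detections: pd.DataFrame,
                          n_frames: int | None = None,
                          interval_s: float = 1.0) -> TrajectorySet:
    """Group detections by identity into frame-ordered trajectories.

    Duplicate (id, frame) pairs — possible from reflections or false
    positives — are resolved by keeping the detection whose sampled grid
    had the largest mean margin from the binarisation threshold; every
    conflict is logged and counted.  Gaps stay gaps: no interpolation.
    """
    conflicts = 0
    trajectories: dict[int, pd.DataFrame] = {}
    if len(detections):
        for tag_id, grp in detections.groupby("id"):
            dup = grp.duplicated(subset="frame", keep=False)
            if dup.any():
                n_dup = grp.loc[dup, "frame"].nunique()
                conflicts += n_dup
                log.warning("id %s: duplicate detections in %d frame(s), "
                            "keeping the largest-margin one", tag_id, n_dup)
                grp = grp.sort_values(["frame", "margin"]).drop_duplicates(
                    subset="frame", keep="last")
            traj = grp.sort_values("frame").reset_index(drop=True)
            trajectories[int(tag_id)] = traj[
                ["frame", "time_s", "x", "y", "orientation_deg"]]
    if n_frames is None:
        n_frames = int(detections["frame"].max()) + 1 if len(detections) else 0
    return TrajectorySet(trajectories, n_frames, interval_s, conflicts)


def summarize_activity(ts: TrajectorySet) -> pd.DataFrame:
    """Per-identity space-use summary.

    Columns: frames detected, detection rate, total path length (px), net
    displacement (px), bounding-box area and convex-hull area (px^2).
    Single-point trajectories have zero path length and zero hull area.
    """
    from scipy.spatial import ConvexHull, QhullError

    rows = []
    for tag_id in ts.ids:
        t = ts[tag_id]
        xy = t[["x", "y"]].to_numpy()
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        path_length = float(steps.sum())
        net = float(np.linalg.norm(xy[-1] - xy[0]))
        span = xy.max(axis=0) - xy.min(axis=0)
        bbox_area = float(span[0] * span[1])
        hull_area = 0.0
        if len(xy) >= 3:
            try:
                hull_area = float(ConvexHull(xy).volume)  # 2-D: area
            except QhullError:
                hull_area = 0.0
        rows.append({"id": tag_id,
                     "frames_detected": len(t),
                     "detection_rate": len(t) / ts.n_frames if ts.n_frames else np.nan,
                     "path_length_px": path_length,
                     "net_displacement_px": net,
                     "bbox_area_px2": bbox_area,
                     "hull_area_px2": hull_area})
    return pd.DataFrame(rows, columns=["id", "frames_detected", "detection_rate",
                                       "path_length_px", "net_displacement_px",
                                       "bbox_area_px2", "hull_area_px2"])
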