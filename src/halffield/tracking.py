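"""Trajectory recovery from label movies and trajectory-inclusion filtering.

Detection reduces each labelled object in a frame to its unweighted pixel
centroid; linking is a greedy nearest-neighbour assignment between
consecutive frames with a hard distance gate and no gap closing.  Cells whose
tracks are incomplete, leave the observation field, start inside the
exclusion band, or never move (nonviable) are rejected with machine-readable
reason codes, mirroring the inclusion rules of the migration analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .geometry import DishGeometry, FieldLabel, assign_field

#: groups analysed on a half-field dish, i.e. subject to region assignment
HALF_FIELD_GROUPS = frozenset({"in-field", "out-of-field"})

#: default linking gate: 30 um per 15-min frame (~120 um/h), roughly an
#: order of magnitude above the observed median cell speed
DEFAULT_MAX_STEP_UM = 30.0

#: total path length (um) below which a complete track is called nonviable
DEFAULT_MOTION_FLOOR_UM = 0.1

TRAJECTORY_COLUMNS = ["replicate", "group", "cell_id", "frame", "t_min", "x_um", "y_um"]


class RejectReason(str, Enum):
    INCOMPLETE = "INCOMPLETE"
    EXITED_FIELD = "EXITED_FIELD"
    EXCLUDED_REGION = "EXCLUDED_REGION"
    NONVIABLE = "NONVIABLE"


@dataclass
class Trajectory:
    """One cell's time-ordered 2D positions at a uniform frame interval.

    Positions are in micrometres in the dish coordinate frame (origin at the
    dish centre).  ``complete`` is true iff the track spans every frame of
    the movie it came from; ``start_frame`` locates partial tracks.
    """

    cell_id: int
    positions: np.ndarray  # (n, 2) float array, columns x_um, y_um
    frame_interval: float  # minutes
    replicate: int = 0
    group: str = "control"
    complete: bool = True
    start_frame: int = 0
    region: FieldLabel | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class DetectionFrame:
    """Centroids (um) detected in one movie frame, with transient ids."""

    frame_index: int
    centroids: np.ndarray  # (k, 2) float array, columns x_um, y_um

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_centroids(
    label_image: np.ndarray, pixel_size: float, frame_index: int = 0
) -> DetectionFrame:
    """Reduce a 2D integer label image to one centroid per nonzero label.

    The centroid is the unweighted mean of member pixel centres (the pixel
    at row r, column c has its centre at (r, c) in pixel units), converted
    to micrometres as ``x = col * pixel_size``, ``y = row * pixel_size``.
    An empty image yields an empty DetectionFrame.
    """
    label_image = np.asarray(label_image)
    if label_image.ndim != 2:
        raise ValueError("label image must be 2D")
    if label_image.size and label_image.min() < 0:
        raise ValueError("label image must be a nonnegative integer array")
    props = regionprops(label_image.astype(np.int64, copy=False))
    centroids = np.array(
        [(p.centroid[1] * pixel_size, p.centroid[0] * pixel_size) for p in props],
        dtype=float,
    ).reshape(-1, 2)
    return DetectionFrame(frame_index=frame_index, centroids=centroids)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_trajectories(
    frames: Sequence[DetectionFrame],
    max_step: float = DEFAULT_MAX_STEP_UM,
    frame_interval: float = 15.0,
    replicate: int = 0,
    group: str = "control",
) -> list[Trajectory]:
    """Link per-frame detections into trajectories by greedy nearest neighbour.

    For each consecutive frame pair, candidate (track end, detection) pairs
    are taken in ascending distance order; a pair is linked when neither
    member is already taken and the distance does not exceed ``max_step``.
    Unmatched detections start new tracks; unmatched tracks terminate (no
    gap closing).  Completeness is judged against the number of frames.
    """
    if max_step <= 0:
        raise ValueError("max_step must be > 0")
    n_frames = len(frames)
    active: list[dict] = []  # each: {"start": int, "points": [xy, ...]}
    finished: list[dict] = []

    for f_idx, det in enumerate(frames):
        pts = det.centroids
        if f_idx == 0:
            active = [{"start": 0, "points": [p]} for p in pts]
            continue
        ends = np.array([t["points"][-1] for t in active], dtype=float).reshape(-1, 2)
        n_a, n_d = len(active), len(pts)
        matched_a = np.zeros(n_a, dtype=bool)
        matched_d = np.zeros(n_d, dtype=bool)
        if n_a and n_d:
            dist = np.linalg.norm(ends[:, None, :] - pts[None, :, :], axis=2)
            order = np.argsort(dist, axis=None, kind="stable")
            for flat in order:
                i, j = divmod(int(flat), n_d)
                if dist[i, j] > max_step:
                    break
                if matched_a[i] or matched_d[j]:
                    continue
                matched_a[i] = matched_d[j] = True
                active[i]["points"].append(pts[j])
        finished.extend(t for i, t in enumerate(active) if not matched_a[i])
        active = [t for i, t in enumerate(active) if matched_a[i]]
        active.extend({"start": f_idx, "points": [p]} for p in pts[~matched_d])
    finished.extend(active)

    finished.sort(key=lambda t: (t["start"], t["points"][0][0], t["points"][0][1]))
    return [
        Trajectory(
            cell_id=cid,
            positions=np.asarray(t["points"], dtype=float),
            frame_interval=frame_interval,
            replicate=replicate,
            group=group,
            complete=(t["start"] == 0 and len(t["points"]) == n_frames),
            start_frame=t["start"],
        )
        for cid, t in enumerate(finished)
    ]


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------

def filter_trajectories(
    trajectories: Iterable[Trajectory],
    n_frames: int,
    dish: DishGeometry,
    motion_floor: float | None = DEFAULT_MOTION_FLOOR_UM,
) -> tuple[list[Trajectory], list[tuple[Trajectory, RejectReason]]]:
    """Apply the trajectory-inclusion rules; return (kept, rejected+reason).

    A track is kept when it (a) spans all ``n_frames`` frames, (b) stays
    inside the observation field (the dish) throughout, (c) starts outside
    the exclusion band — for half-field groups its first-frame region must
    be IN_FIELD or OUT_OF_FIELD, for Control/Uniform dishes any in-dish
    position qualifies — and (d) moves more than ``motion_floor`` um in
    total (nonviability screen; pass None to disable).  Region labels are
    assigned from the first-frame position; kept tracks carry their region.
    The filter is idempotent: re-filtering the kept set changes nothing.
    """
    kept: list[Trajectory] = []
    rejected: list[tuple[Trajectory, RejectReason]] = []
    radius_um = dish.radius * 1000.0
    for traj in trajectories:
        if not traj.complete or len(traj) != n_frames:
            rejected.append((traj, RejectReason.INCOMPLETE))
            continue
        if np.any(np.hypot(traj.positions[:, 0], traj.positions[:, 1]) > radius_um):
            rejected.append((traj, RejectReason.EXITED_FIELD))
            continue
        first_mm = (traj.positions[0, 0] / 1000.0, traj.positions[0, 1] / 1000.0)
        label = assign_field(first_mm, dish)
        if traj.group in HALF_FIELD_GROUPS:
            if label not in (FieldLabel.IN_FIELD, FieldLabel.OUT_OF_FIELD):
                rejected.append((traj, RejectReason.EXCLUDED_REGION))
                continue
        if motion_floor is not None:
            steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
            if steps.sum() < motion_floor:
                rejected.append((traj, RejectReason.NONVIABLE))
                continue
        traj.region = label
        kept.append(traj)
    return kept, rejected


# ---------------------------------------------------------------------------
# tabular interchange
# ---------------------------------------------------------------------------

def trajectories_to_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """Long-format table: one row per cell per frame (positions in um)."""
    trajs = list(trajectories)
    if not trajs:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    lengths = np.array([len(t) for t in trajs])
    frames = np.concatenate(
        [np.arange(t.start_frame, t.start_frame + len(t)) for t in trajs]
    )
    intervals = np.repeat([t.frame_interval for t in trajs], lengths)
    positions = np.concatenate([t.positions for t in trajs])
    return pd.DataFrame(
        {
            "replicate": np.repeat([t.replicate for t in trajs], lengths),
            "group": np.repeat([t.group for t in trajs], lengths),
            "cell_id": np.repeat([t.cell_id for t in trajs], lengths),
            "frame": frames,
            "t_min": frames * intervals,
            "x_um": positions[:, 0],
            "y_um": positions[:, 1],
        }
    )


def frame_to_trajectories(df: pd.DataFrame, n_frames: int | None = None) -> list[Trajectory]:
    """Rebuild Trajectory objects from a long-format trajectory table."""
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table lacks columns: {missing}")
    out: list[Trajectory] = []
    for (rep, group, cid), sub in df.groupby(
        ["replicate", "group", "cell_id"], sort=True
    ):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) != 1):
            raise ValueError(
                f"trajectory (replicate={rep}, group={group}, cell={cid}) has frame gaps"
            )
        t_min = sub["t_min"].to_numpy()
        interval = float(t_min[1] - t_min[0]) if len(t_min) > 1 else 15.0
        total = n_frames if n_frames is not None else len(frames)
        out.append(
            Trajectory(
                cell_id=int(cid),
                positions=sub[["x_um", "y_um"]].to_numpy(dtype=float),
                frame_interval=interval,
                replicate=int(rep),
                group=str(group),
                complete=(frames[0] == 0 and len(frames) == total),
                start_frame=int(frames[0]),
            )
        )
    return out
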