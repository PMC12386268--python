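"""Per-cell and ensemble migration statistics.

Per cell: total path length, net (straight-line) displacement, and velocity.
Per cohort: the ensemble mean squared displacement (MSD) from each cell's
initial position,

    MSD(t) = (1/N) * sum_i || x_i(t) - x_i(0) ||^2 ,

fit by ordinary least squares against elapsed time.  Linear MSD growth is
the signature of diffusive (random-walk) motion; the coefficient of
determination R^2 of the fit quantifies linearity, and a track population is
called random-walk consistent when R^2 reaches a configurable threshold.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .tracking import Trajectory

VelocityMode = Literal["path_over_time", "mean_step_speed"]

#: default R^2 above which an MSD curve is considered linear
DEFAULT_R2_THRESHOLD = 0.99

METRICS_COLUMNS = [
    "replicate",
    "group",
    "cell_id",
    "velocity_umph",
    "total_distance_um",
    "net_displacement_um",
]


@dataclass(frozen=True)
class MigrationMetrics:
    cell_id: int
    velocity: float  # um/h
    total_distance: float  # um
    net_displacement: float  # um
    n_steps: int


@dataclass(frozen=True)
class MSDCurve:
    """Ensemble MSD versus elapsed time with its linear fit.

    ``lags`` are hours t = k * dt for k = 1..K; ``msd`` the ensemble mean
    squared displacement (um^2) at each lag; the fit is ordinary least
    squares with a free intercept over all K lags.
    """

    lags: np.ndarray  # hours
    msd: np.ndarray  # um^2
    n_cells: int
    fit_slope: float  # um^2/h
    fit_intercept: float  # um^2
    r_squared: float


def _steps(traj: Trajectory) -> np.ndarray:
    if len(traj) < 2:
        raise ValueError("trajectory needs at least 2 positions")
    return np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)


def total_distance(traj: Trajectory) -> float:
    """Cumulative path length (um): sum of frame-to-frame step lengths."""
    return float(_steps(traj).sum())


def net_displacement(traj: Trajectory) -> float:
    """Straight-line distance (um) between first and last positions."""
    if len(traj) < 2:
        raise ValueError("trajectory needs at least 2 positions")
    return float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))


def velocity(traj: Trajectory, mode: VelocityMode = "path_over_time") -> float:
    """Migration velocity in um/h.

    ``path_over_time`` divides the total path length by the elapsed time;
    ``mean_step_speed`` averages per-step speeds.  The two coincide exactly
    when the frame interval is uniform (as here), and both are exposed
    because published velocity figures rarely state which was used.
    """
    steps = _steps(traj)
    hours_per_step = traj.frame_interval / 60.0
    if mode == "path_over_time":
        return float(steps.sum() / (len(steps) * hours_per_step))
    if mode == "mean_step_speed":
        return float(np.mean(steps / hours_per_step))
    raise ValueError(f"unknown velocity mode: {mode!r}")


def compute_metrics(
    traj: Trajectory, mode: VelocityMode = "path_over_time"
) -> MigrationMetrics:
    return MigrationMetrics(
        cell_id=traj.cell_id,
        velocity=velocity(traj, mode),
        total_distance=total_distance(traj),
        net_displacement=net_displacement(traj),
        n_steps=len(traj) - 1,
    )


def metrics_table(
    trajectories: Iterable[Trajectory], mode: VelocityMode = "path_over_time"
) -> pd.DataFrame:
    """Per-cell metrics as a tidy table (one row per trajectory)."""
    rows = []
    for traj in trajectories:
        m = compute_metrics(traj, mode)
        rows.append(
            {
                "replicate": traj.replicate,
                "group": traj.group,
                "cell_id": traj.cell_id,
                "velocity_umph": m.velocity,
                "total_distance_um": m.total_distance,
                "net_displacement_um": m.net_displacement,
            }
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def ensemble_msd(trajectories: Sequence[Trajectory]) -> MSDCurve:
    """Ensemble MSD from the initial position, with its linear fit.

    All trajectories must be complete and of equal length; displacement is
    measured from each cell's own first-frame position (no time averaging
    over sliding windows).  The least-squares line has a free intercept:
    localisation noise in real data shifts the whole curve upward without
    affecting the slope, so forcing the line through zero would bias it.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("ensemble_msd needs at least one trajectory")
    lengths = {len(t) for t in trajs}
    if len(lengths) != 1:
        raise ValueError(f"trajectories have ragged lengths: {sorted(lengths)}")
    (n_pos,) = lengths
    if n_pos < 2:
        raise ValueError("trajectories need at least 2 positions")
    dt_h = trajs[0].frame_interval / 60.0
    pos = np.stack([t.positions for t in trajs])  # (N, T, 2)
    disp2 = np.sum((pos - pos[:, :1, :]) ** 2, axis=2)  # (N, T)
    msd = disp2.mean(axis=0)[1:]  # drop the trivially-zero lag 0
    lags = np.arange(1, n_pos) * dt_h
    slope, intercept = np.polyfit(lags, msd, 1)
    ss_res = float(np.sum((msd - (intercept + slope * lags)) ** 2))
    ss_tot = float(np.sum((msd - msd.mean()) ** 2))
    # a flat curve (ss_tot = 0) is fit exactly by its own constant
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MSDCurve(
        lags=lags,
        msd=msd,
        n_cells=len(trajs),
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        r_squared=float(r2),
    )


def classify_motion(
    curve: MSDCurve, r2_threshold: float = DEFAULT_R2_THRESHOLD
) -> str:
    """Label an MSD curve RANDOM_WALK_CONSISTENT or NOT_LINEAR.

    The label is a convenience summary reported alongside R^2, never in
    place of it; needs at least 3 lags for the fit to be meaningful.
    """
    if len(curve.lags) < 3:
        raise ValueError("motion classification needs at least 3 lags")
    return (
        "RANDOM_WALK_CONSISTENT" if curve.r_squared >= r2_threshold else "NOT_LINEAR"
    )


def msd_table(curve: MSDCurve, group: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"group": group, "lag_h": curve.lags, "msd_um2": curve.msd}
    )
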