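"""Synthetic time-lapse migration data with the statistical structure the
analysis pipeline assumes.

Cells perform random walks (optionally with directional persistence) at
per-cell speeds drawn from a lognormal law, over a 24 h movie sampled every
15 min (97 frames).  Calibration presets pin each experimental group's speed
law to published median/IQR velocity summaries for the half-field
irradiation experiment, with and without cisplatin; a FUCCI preset models
the cisplatin-induced G2 arrest (~70.3% of cells in the green S/G2/M
state).  A small renderer turns trajectories into integer-label TIFF movies
so the tracking stage can be validated end to end against known ground
truth.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import disk as draw_disk

from .geometry import DishGeometry
from .tracking import Trajectory

#: Phi^{-1}(0.75): quartiles of lognormal(mu, sigma) sit at exp(mu -/+ z75*sigma)
Z75 = 0.6744897501960817

#: printed per-group velocity quartiles (q1, median, q3) in um/h used to
#: calibrate the lognormal speed law; "fig2" = radiation alone,
#: "fig4" = cisplatin + radiation
VELOCITY_QUARTILES: dict[str, dict[str, tuple[float, float, float]]] = {
    "fig2": {
        "control": (3.31, 5.73, 9.49),
        "uniform": (2.90, 4.99, 8.36),
        "in-field": (3.35, 5.86, 9.78),
        "out-of-field": (2.68, 4.66, 7.84),
    },
    "fig4": {
        "control": (2.66, 4.83, 8.11),
        "uniform": (3.05, 5.28, 8.86),
        "in-field": (2.92, 5.03, 8.21),
        "out-of-field": (3.04, 5.17, 8.32),
    },
}

#: FUCCI state probabilities (G1_red, earlyS_yellow, SG2M_green).  The
#: cisplatin green fraction is the published arrest level; the remaining
#: mass and the untreated ("control") distribution are synthetic stand-ins
#: for an asynchronously cycling population.
FUCCI_PRESETS: dict[str, tuple[float, float, float]] = {
    "control": (0.40, 0.15, 0.45),
    "cisplatin": (0.200, 0.097, 0.703),
}

STATE_NAMES = ("red", "yellow", "green")


class CellCycleState(str, Enum):
    """FUCCI reporter state: G1 red, early-S yellow, S/G2/M green."""

    G1_red = "red"
    earlyS_yellow = "yellow"
    SG2M_green = "green"


def fit_log_sigma(q1: float, median: float, q3: float) -> float:
    """Lognormal log-scale sigma whose quartiles best match a printed IQR.

    With mu fixed at log(median), least squares over the two log-ratios
    log(q1/median) and log(q3/median) gives sigma = log(q3/q1) / (2 * z75).
    """
    if not 0 < q1 <= median <= q3:
        raise ValueError("quartiles must satisfy 0 < q1 <= median <= q3")
    return float(np.log(q3 / q1) / (2.0 * Z75))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings for one synthetic experiment.

    ``n_cells_per_group`` is the total cell count per experimental group,
    split as evenly as possible across ``n_replicates`` dishes.
    ``speed_median`` (um/h), ``speed_log_sigma`` and ``persistence`` are
    per-group maps; persistence 0 is a pure random walk.  ``step_law``
    selects how per-frame displacements realise a cell's speed:
    ``fixed_length`` steps of exactly speed * interval (the calibration
    default: the path-length velocity estimator then recovers the drawn
    speed exactly), or ``gaussian`` isotropic Gaussian steps whose mean
    length equals speed * interval.
    """

    n_cells_per_group: int
    speed_median: Mapping[str, float]
    speed_log_sigma: Mapping[str, float]
    persistence: Mapping[str, float] = field(default_factory=dict)
    n_replicates: int = 3
    n_frames: int = 97
    frame_interval: float = 15.0  # minutes
    dish: DishGeometry = field(default_factory=DishGeometry)
    fucci_distribution: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(FUCCI_PRESETS)
    )
    seed: int = 0
    step_law: str = "fixed_length"
    cell_radius: float = 5.0  # um; also the start-position margin

    def __post_init__(self) -> None:
        if self.n_cells_per_group < 1 or self.n_replicates < 1:
            raise ValueError("n_cells_per_group and n_replicates must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.step_law not in ("fixed_length", "gaussian"):
            raise ValueError(f"unknown step_law: {self.step_law!r}")
        for g, m in self.speed_median.items():
            if m < 0:
                raise ValueError(f"speed_median[{g!r}] must be >= 0")
        for g, s in self.speed_log_sigma.items():
            if s < 0:
                raise ValueError(f"speed_log_sigma[{g!r}] must be >= 0")
        for g, p in self.persistence.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"persistence[{g!r}] must lie in [0, 1)")
        for cond, dist in self.fucci_distribution.items():
            dist = np.asarray(dist, dtype=float)
            if dist.size != 3 or np.any(dist < 0):
                raise ValueError(
                    f"fucci_distribution[{cond!r}] must be 3 nonnegative entries"
                )
            if abs(dist.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"fucci_distribution[{cond!r}] must sum to 1 (got {dist.sum()})"
                )

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.speed_median.keys())


def preset_config(
    name: str, n_cells_per_group: int = 1000, seed: int = 0, **overrides
) -> SyntheticConfig:
    """Build a SyntheticConfig from a named calibration preset.

    ``fig2`` / ``fig4`` give all four groups of the corresponding
    experiment; ``fig2-<group>`` / ``fig4-<group>`` restrict to one group;
    ``null`` gives four groups that all share the radiation-alone Control
    speed law (a global-null experiment).
    """
    if name in VELOCITY_QUARTILES:
        table = VELOCITY_QUARTILES[name]
        groups = dict(table)
    elif name == "null":
        groups = {g: VELOCITY_QUARTILES["fig2"]["control"] for g in VELOCITY_QUARTILES["fig2"]}
    elif "-" in name and name.split("-", 1)[0] in VELOCITY_QUARTILES:
        exp, group = name.split("-", 1)
        table = VELOCITY_QUARTILES[exp]
        if group not in table:
            raise KeyError(
                f"unknown group {group!r}; available: {sorted(table)}"
            )
        groups = {group: table[group]}
    else:
        known = sorted(VELOCITY_QUARTILES) + ["null"] + [
            f"{e}-{g}" for e in VELOCITY_QUARTILES for g in VELOCITY_QUARTILES[e]
        ]
        raise KeyError(f"unknown preset {name!r}; available: {known}")
    return SyntheticConfig(
        n_cells_per_group=n_cells_per_group,
        speed_median={g: q[1] for g, q in groups.items()},
        speed_log_sigma={g: fit_log_sigma(*q) for g, q in groups.items()},
        persistence={g: 0.0 for g in groups},
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _stream(seed: int, group: str, replicate: int, purpose: int = 0) -> np.random.Generator:
    """Deterministic per-(group, replicate) random stream from a master seed."""
    tag = zlib.crc32(group.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), tag, int(replicate), int(purpose)])
    )


def _sample_starts(
    rng: np.random.Generator, n: int, group: str, dish: DishGeometry, margin_um: float
) -> np.ndarray:
    """Uniform start positions (um) in the group's analyzable sub-region.

    Half-field groups start in their own half, at least ``margin_um`` from
    the exclusion-band edge; every group keeps the margin from the dish rim.
    """
    r_max = dish.radius * 1000.0 - margin_um
    if r_max <= 0:
        raise ValueError("cell_radius margin exceeds the dish radius")
    bx = dish.boundary_x * 1000.0
    w = dish.exclusion_half_width * 1000.0
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(-r_max, r_max, size=(2 * (n - filled) + 16, 2))
        ok = np.hypot(cand[:, 0], cand[:, 1]) <= r_max
        if group == "in-field":
            ok &= cand[:, 0] < bx - w - margin_um
        elif group == "out-of-field":
            ok &= cand[:, 0] > bx + w + margin_um
        cand = cand[ok]
        take = min(len(cand), n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def simulate_trajectories(config: SyntheticConfig, group: str) -> list[Trajectory]:
    """Simulate one group's trajectories; reproducible from the config seed.

    Each cell draws a speed from lognormal(log(median), sigma); per-frame
    step directions are uniform on the circle, blended with the previous
    direction by the group's persistence weight; step lengths follow the
    configured step law.  Cells start uniformly in the group's analyzable
    sub-region and never divide, die, or interact.
    """
    if group not in config.speed_median:
        raise KeyError(
            f"group {group!r} has no speed_median entry; "
            f"configured groups: {sorted(config.speed_median)}"
        )
    median = config.speed_median[group]
    sigma = config.speed_log_sigma.get(group, 0.0)
    rho = config.persistence.get(group, 0.0)
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"persistence must lie in [0, 1), got {rho}")
    dt_h = config.frame_interval / 60.0
    n_steps = config.n_frames - 1

    base, extra = divmod(config.n_cells_per_group, config.n_replicates)
    trajectories: list[Trajectory] = []
    cell_id = 0
    for rep in range(config.n_replicates):
        n = base + (1 if rep < extra else 0)
        if n == 0:
            continue
        rng = _stream(config.seed, group, rep)
        speeds = median * np.exp(sigma * rng.standard_normal(n))
        starts = _sample_starts(rng, n, group, config.dish, config.cell_radius)

        mean_len = speeds * dt_h  # um per frame
        if config.step_law == "fixed_length":
            lengths = np.broadcast_to(mean_len, (n_steps, n))
        else:  # gaussian: isotropic with E|step| = mean_len
            axis_sd = mean_len * np.sqrt(2.0 / np.pi)
            lengths = axis_sd * np.sqrt(
                rng.standard_normal((n_steps, n)) ** 2
                + rng.standard_normal((n_steps, n)) ** 2
            )

        pos = np.empty((n, config.n_frames, 2))
        pos[:, 0, :] = starts
        prev_dir = None
        for k in range(n_steps):
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
            u = np.column_stack([np.cos(theta), np.sin(theta)])
            if rho > 0.0 and prev_dir is not None:
                blend = rho * prev_dir + (1.0 - rho) * u
                norms = np.linalg.norm(blend, axis=1, keepdims=True)
                # a vanishing blend (opposite directions) falls back to the fresh draw
                direction = np.where(norms > 1e-12, blend / np.maximum(norms, 1e-12), u)
            else:
                direction = u
            pos[:, k + 1, :] = pos[:, k, :] + lengths[k][:, None] * direction
            prev_dir = direction

        for i in range(n):
            trajectories.append(
                Trajectory(
                    cell_id=cell_id,
                    positions=pos[i],
                    frame_interval=config.frame_interval,
                    replicate=rep,
                    group=group,
                    complete=True,
                    start_frame=0,
                )
            )
            cell_id += 1
    return trajectories


def simulate_experiment(config: SyntheticConfig) -> list[Trajectory]:
    """Simulate every configured group."""
    out: list[Trajectory] = []
    for group in config.groups:
        out.extend(simulate_trajectories(config, group))
    return out


# ---------------------------------------------------------------------------
# FUCCI cell-cycle states
# ---------------------------------------------------------------------------

def sample_cellcycle_states(
    n: int, distribution: Sequence[float], seed: int | None = None
) -> list[CellCycleState]:
    """Draw n i.i.d. FUCCI states from (red, yellow, green) probabilities."""
    dist = np.asarray(distribution, dtype=float)
    if dist.size != 3 or np.any(dist < 0):
        raise ValueError("distribution must be 3 nonnegative probabilities")
    if abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError(f"distribution must sum to 1, got {dist.sum()}")
    rng = np.random.default_rng(seed)
    draws = rng.choice(3, size=n, p=dist / dist.sum())
    states = [CellCycleState.G1_red, CellCycleState.earlyS_yellow, CellCycleState.SG2M_green]
    return [states[i] for i in draws]


def state_fractions(states: Sequence[CellCycleState]) -> dict[str, float]:
    n = len(states)
    return {
        name: sum(1 for s in states if s.value == name) / n for name in STATE_NAMES
    }


# ---------------------------------------------------------------------------
# label-movie rendering
# ---------------------------------------------------------------------------

@dataclass
class LabelMovie:
    """Stack of 2D integer label images (label 0 = background)."""

    frames: np.ndarray  # (T, H, W) unsigned integer labels
    pixel_size: float  # um/pixel
    frame_interval: float  # minutes

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")

    def save(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames.astype(np.uint16))

    @classmethod
    def load(cls, path, pixel_size: float, frame_interval: float = 15.0) -> "LabelMovie":
        import tifffile

        return cls(
            frames=tifffile.imread(path),
            pixel_size=pixel_size,
            frame_interval=frame_interval,
        )


def render_label_movie(
    trajectories: Sequence[Trajectory],
    pixel_size: float,
    cell_radius: float,
    image_shape: tuple[int, int],
    origin: tuple[float, float] = (0.0, 0.0),
) -> LabelMovie:
    """Rasterise trajectories as disks with persistent integer labels.

    Position (x, y) um maps to pixel (row, col) = ((y - oy) / pixel_size,
    (x - ox) / pixel_size).  Every disk must fit inside the image and disks
    in the same frame must not overlap (the fixture guarantees
    separability; overlap is an error, not something to resolve).  Each
    cell keeps label cell_id + 1 across frames, so the round trip through
    detection recovers the source positions to within a pixel.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories to render")
    lengths = {len(t) for t in trajs}
    if len(lengths) != 1:
        raise ValueError("all trajectories must cover the same frames")
    (n_frames,) = lengths
    h, w = image_shape
    r_px = cell_radius / pixel_size
    frames = np.zeros((n_frames, h, w), dtype=np.uint16)
    for f in range(n_frames):
        for traj in trajs:
            x, y = traj.positions[f]
            row = (y - origin[1]) / pixel_size
            col = (x - origin[0]) / pixel_size
            if not (
                r_px <= row <= h - 1 - r_px and r_px <= col <= w - 1 - r_px
            ):
                raise ValueError(
                    f"cell {traj.cell_id} frame {f} does not fit in the image"
                )
            rr, cc = draw_disk((row, col), r_px + 0.5, shape=(h, w))
            if np.any(frames[f, rr, cc]):
                raise ValueError(
                    f"overlapping cells in frame {f}: the rendering fixture "
                    "requires separable disks"
                )
            frames[f, rr, cc] = traj.cell_id + 1
    return LabelMovie(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=trajs[0].frame_interval,
    )


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)
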