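"""End-to-end orchestration: generate -> (track) -> classify/filter ->
measure -> test, with a structured config, per-stage logging, and
machine-readable outputs.

Every stage writes plain CSV/JSON so any stage can be replaced by external
data (e.g. real tracking output dropped in at the metrics stage).  A run is
fully determined by its config and master seed; the run record captures the
config snapshot, per-stage row counts, the rejection tally, and SHA-256
digests of the primary outputs so reproducibility can be checked byte for
byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .geometry import DishGeometry, analyzable_fraction
from .metrics import classify_motion, ensemble_msd, metrics_table, msd_table
from .stats import GROUP_ORDER, chi_square_test, steel_test, summarize_groups
from .synthetic import (
    FUCCI_PRESETS,
    STATE_NAMES,
    SyntheticConfig,
    preset_config,
    sample_cellcycle_states,
    simulate_trajectories,
)
from .tracking import filter_trajectories, trajectories_to_frame

logger = logging.getLogger("halffield")

_CONFIG_KEYS = {f.name for f in dataclasses.fields(SyntheticConfig)}
_DISH_KEYS = {f.name for f in dataclasses.fields(DishGeometry)}

#: significance threshold used when flagging comparisons in reports
ALPHA = 0.05


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def config_to_dict(config: SyntheticConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["speed_median"] = dict(config.speed_median)
    d["speed_log_sigma"] = dict(config.speed_log_sigma)
    d["persistence"] = dict(config.persistence)
    d["fucci_distribution"] = {
        k: list(v) for k, v in config.fucci_distribution.items()
    }
    return d


def config_from_dict(data: Mapping[str, Any]) -> SyntheticConfig:
    unknown = sorted(set(data) - _CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    kwargs = dict(data)
    if "dish" in kwargs and kwargs["dish"] is not None:
        dish = kwargs["dish"]
        if isinstance(dish, Mapping):
            bad = sorted(set(dish) - _DISH_KEYS)
            if bad:
                raise ValueError(f"unknown dish keys: {bad}")
            kwargs["dish"] = DishGeometry(**dish)
    if "fucci_distribution" in kwargs and kwargs["fucci_distribution"] is not None:
        kwargs["fucci_distribution"] = {
            k: tuple(v) for k, v in kwargs["fucci_distribution"].items()
        }
    return SyntheticConfig(**kwargs)


def load_config(path: str | Path) -> SyntheticConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def validate_config(path: str | Path) -> list[str]:
    """Validate a config file; return actionable findings (empty = valid)."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise OSError(f"cannot read config file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        return [f"not parseable as YAML: {exc}"]
    if not isinstance(data, Mapping):
        return ["config must be a YAML mapping"]
    try:
        config_from_dict(data)
    except (ValueError, TypeError, KeyError) as exc:
        return [str(exc)]
    return []


def resolve_config(
    source: str | Path | SyntheticConfig,
    seed: int | None = None,
    n_cells_per_group: int | None = None,
) -> SyntheticConfig:
    """Accept a SyntheticConfig, a YAML path, or a preset name."""
    if isinstance(source, SyntheticConfig):
        cfg = source
    elif Path(str(source)).exists():
        cfg = load_config(source)
    else:
        cfg = preset_config(
            str(source), n_cells_per_group=n_cells_per_group or 1000
        )
        n_cells_per_group = None  # already applied
    updates = {}
    if seed is not None:
        updates["seed"] = seed
    if n_cells_per_group is not None:
        updates["n_cells_per_group"] = n_cells_per_group
    return dataclasses.replace(cfg, **updates) if updates else cfg


# ---------------------------------------------------------------------------
# run record
# ---------------------------------------------------------------------------

@dataclass
class PipelineRunRecord:
    config: dict[str, Any]
    seed: int
    stage_counts: dict[str, int]
    rejection_tally: dict[str, int]
    output_digests: dict[str, str]
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # pyarrow writes large trajectory tables an order of magnitude faster
    # than pandas and uses shortest-roundtrip float representation
    import pyarrow as pa
    import pyarrow.csv as pacsv

    pacsv.write_csv(pa.Table.from_pandas(df, preserve_index=False), path)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_experiment(
    config: str | Path | SyntheticConfig,
    out_dir: str | Path,
    seed: int | None = None,
    fucci_n: int | None = None,
    write_trajectories: bool = True,
) -> PipelineRunRecord:
    """Run the full synthetic experiment and write all stage outputs.

    ``config`` may be a SyntheticConfig, a preset name (``fig2``, ``fig4``,
    ``null``), or a path to a YAML config.  ``seed`` overrides the config's
    master seed.  Outputs under ``out_dir``: trajectories.csv (all
    generated tracks), kept_trajectories.csv / rejected_trajectories.csv,
    metrics.csv, msd.csv + msd_fits.json, fucci_states.csv, stats.json and
    run_record.json.  ``write_trajectories=False`` skips the (large)
    per-frame trajectory CSVs while keeping every derived output.
    """
    started = datetime.now(timezone.utc).isoformat()
    cfg = resolve_config(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate
    all_trajs = []
    for group in cfg.groups:
        trajs = simulate_trajectories(cfg, group)
        logger.info("simulate: group %s -> %d trajectories", group, len(trajs))
        all_trajs.extend(trajs)
    if write_trajectories:
        _write_csv(trajectories_to_frame(all_trajs), out / "trajectories.csv")

    # --- classify + filter
    kept, rejected = filter_trajectories(all_trajs, cfg.n_frames, cfg.dish)
    tally: dict[str, int] = {}
    for _, reason in rejected:
        tally[reason.value] = tally.get(reason.value, 0) + 1
    logger.info("filter: kept %d, rejected %d (%s)", len(kept), len(rejected), tally)
    if write_trajectories:
        _write_csv(trajectories_to_frame(kept), out / "kept_trajectories.csv")
        rej_df = trajectories_to_frame([t for t, _ in rejected])
        reason_by_key = {
            (t.replicate, t.group, t.cell_id): r.value for t, r in rejected
        }
        if len(rej_df):
            rej_df["reject_reason"] = [
                reason_by_key[(row.replicate, row.group, row.cell_id)]
                for row in rej_df.itertuples()
            ]
        else:
            rej_df["reject_reason"] = pd.Series(dtype=str)
        _write_csv(rej_df, out / "rejected_trajectories.csv")

    # --- per-cell metrics
    mdf = metrics_table(kept)
    _write_csv(mdf, out / "metrics.csv")

    # --- ensemble MSD per group
    msd_frames, fits = [], {}
    for group in cfg.groups:
        gtrajs = [t for t in kept if t.group == group]
        if not gtrajs:
            continue
        curve = ensemble_msd(gtrajs)
        msd_frames.append(msd_table(curve, group))
        fits[group] = {
            "slope_um2_per_h": curve.fit_slope,
            "intercept_um2": curve.fit_intercept,
            "r_squared": curve.r_squared,
            "n_cells": curve.n_cells,
            "motion_class": classify_motion(curve),
        }
    if msd_frames:
        _write_csv(pd.concat(msd_frames, ignore_index=True), out / "msd.csv")
    (out / "msd_fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))

    # --- FUCCI states
    n_fucci = fucci_n if fucci_n is not None else cfg.n_cells_per_group
    fucci_rows, fucci_counts = [], {}
    for i, (cond, dist) in enumerate(sorted(cfg.fucci_distribution.items())):
        states = sample_cellcycle_states(
            n_fucci, dist, seed=np.random.SeedSequence([cfg.seed, 0x46CC, i])
        )
        fucci_counts[cond] = [
            sum(1 for s in states if s.value == name) for name in STATE_NAMES
        ]
        fucci_rows.extend(
            {"condition": cond, "cell_id": j, "state": s.value}
            for j, s in enumerate(states)
        )
    _write_csv(pd.DataFrame(fucci_rows), out / "fucci_states.csv")

    # --- statistics
    stats_report = build_stats_report(mdf, fucci_counts)
    stats_report["qc"] = {
        "analyzable_fraction": analyzable_fraction(cfg.dish),
        "cells_per_group": {
            g: int((mdf["group"] == g).sum()) for g in cfg.groups
        },
    }
    (out / "stats.json").write_text(json.dumps(stats_report, indent=2, sort_keys=True))

    record = PipelineRunRecord(
        config=config_to_dict(cfg),
        seed=cfg.seed,
        stage_counts={
            "generated": len(all_trajs),
            "kept": len(kept),
            "rejected": len(rejected),
            "metrics_rows": len(mdf),
        },
        rejection_tally=tally,
        output_digests={
            p.name: _digest(p)
            for p in sorted(out.glob("*.csv")) + [out / "stats.json", out / "msd_fits.json"]
        },
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    (out / "run_record.json").write_text(record.to_json())
    return record


def build_stats_report(
    metrics_df: pd.DataFrame, fucci_counts: Mapping[str, list[int]] | None = None
) -> dict[str, Any]:
    """Steel comparisons vs control, chi-square on FUCCI counts, summaries."""
    report: dict[str, Any] = {"alpha": ALPHA}
    groups = list(metrics_df["group"].unique())
    ordered = [g for g in GROUP_ORDER if g in groups] + sorted(
        g for g in groups if g not in GROUP_ORDER
    )

    for metric, col in (
        ("velocity", "velocity_umph"),
        ("total_distance", "total_distance_um"),
        ("net_displacement", "net_displacement_um"),
    ):
        values = {
            g: metrics_df.loc[metrics_df["group"] == g, col].to_numpy()
            for g in ordered
        }
        report.setdefault("summaries", {})[metric] = [
            dataclasses.asdict(s) for s in summarize_groups(values)
        ]
        if "control" in values and len(values) > 1:
            treatments = {g: v for g, v in values.items() if g != "control"}
            res = steel_test(values["control"], treatments, mode="mvn")
            report.setdefault("steel", {})[metric] = [
                {
                    "group": g,
                    "z": float(res.z_stats[i]),
                    "p_adjusted": float(res.p_adjusted[i]),
                    "significant": bool(res.p_adjusted[i] < ALPHA),
                    "method": res.method,
                    "mc_error": float(res.mc_error[i]),
                }
                for i, g in enumerate(res.treatments)
            ]

    if fucci_counts:
        conds = sorted(fucci_counts)
        table = np.array([fucci_counts[c] for c in conds], dtype=float)
        if len(conds) >= 2:
            chi = chi_square_test(table)
            report["chi_square"] = {
                "conditions": conds,
                "states": list(STATE_NAMES),
                "observed": table.astype(int).tolist(),
                "statistic": chi.statistic,
                "df": chi.df,
                "p_value": chi.p_value,
                "expected": chi.expected.tolist(),
            }
    return report
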