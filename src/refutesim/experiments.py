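"""The four simulation experiments and their summary statistics.

Experiment 1 — time period: iterate the contagion for 30 days for each
initial spreader-emotion band, snapshot the compartment distribution at days
1, 3, 5, 8 and 10, and measure when the compartment counts stabilize.

Experiment 2 — network intimacy: pin the pairwise transmission probability
R_sr to fixed levels (0.2 / 0.5 / 0.8) and compare final emotion-band
proportions over a 10-day horizon.

Experiment 3 — refutation speed x credibility: run a grid of (v, a)
combinations and report the stabilized mean emotion of infected (R-role)
agents.

Experiment 4 — before/after: compare per-agent emotion distributions and
band proportions at day 0 and the final day, starting from a
majority-negative crowd.

Every driver is reproducible bit-for-bit from (config, seed list).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .model_core import PairUpdateVariant, RefutationContext
from .population import InitSpec
from .simulator import Trajectory, run

__all__ = [
    "ExperimentResult",
    "detect_stabilization",
    "stabilized_mean_emotion_r",
    "run_experiment_time_period",
    "run_experiment_intimacy",
    "run_experiment_speed_credibility",
    "run_experiment_before_after",
    "SNAPSHOT_DAYS",
    "DEFAULT_LEVELS",
]

#: Days at which Experiment 1 snapshots the compartment distribution.
SNAPSHOT_DAYS = (1, 3, 5, 8, 10)

#: Level values used for v and a (levels 1, 2, 3) and for R_sr overrides.
DEFAULT_LEVELS = (0.8, 0.5, 0.2)

#: The six (v-level, a-level) combinations of Experiment 3, 1-indexed.
DEFAULT_COMBOS = ((1, 1), (2, 1), (3, 1), (2, 2), (2, 3), (3, 3))


@dataclass
class ExperimentResult:
    """Result of one experiment driver.

    ``cells`` holds one row per (design cell, seed); ``summary`` aggregates
    over seeds per cell; ``extras`` carries experiment-specific tables (e.g.
    snapshots, distributions).
    """

    name: str
    cells: pd.DataFrame
    summary: pd.DataFrame
    extras: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def detect_stabilization(
    series: Sequence[float], tol: float, window: int
) -> int | None:
    """First index from which the series stays within ``tol`` to the end.

    Returns the smallest index ``d`` such that every full length-``window``
    window starting at or after ``d`` has max - min <= tol; ``None`` if no
    such index exists.  Windows containing NaN never qualify.
    """
    x = np.asarray(series, dtype=float)
    if window < 2:
        raise ValueError("window must be at least 2")
    if window > x.size:
        raise ValueError(f"window ({window}) longer than series ({x.size})")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    sw = np.lib.stride_tricks.sliding_window_view(x, window)
    rng = sw.max(axis=1) - sw.min(axis=1)  # NaN-poisoned windows give NaN
    ok = rng <= tol  # NaN compares False
    suffix_ok = np.flip(np.logical_and.accumulate(np.flip(ok)))
    hits = np.nonzero(suffix_ok)[0]
    return int(hits[0]) if hits.size else None


def stabilized_mean_emotion_r(
    trajectory: Trajectory, tol: float = 0.02, window: int = 3
) -> float:
    """Mean emotion of R-role agents over the post-stabilization days.

    Stabilization is detected on the daily mean-E_r series; if the series
    never stabilizes (or R agents appear too late), the mean over the last
    ``window`` days is used.  NaN days (no R agents) are ignored in the
    final mean; the result is NaN only if R agents never exist.
    """
    series = trajectory.records["mean_emotion_r"].to_numpy()
    try:
        d = detect_stabilization(series, tol=tol, window=window)
    except ValueError:
        d = None
    if d is None:
        d = max(series.size - window, 0)
    tail = series[d:]
    if np.all(np.isnan(tail)):
        tail = series
    if np.all(np.isnan(tail)):
        return float("nan")
    return float(np.nanmean(tail))


def _seed_list(seeds: Iterable[int]) -> list[int]:
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed is required")
    return seeds


def _count_stabilization_day(
    records: pd.DataFrame, n: int, tol_frac: float = 0.02, window: int = 3
) -> int | None:
    """Max over the three compartment-count series of their stabilization
    day (absolute tolerance ``tol_frac * n``); None if any never stabilizes."""
    days = []
    for col in ("n_s", "n_r", "n_m"):
        d = detect_stabilization(records[col].to_numpy(), tol=tol_frac * n, window=window)
        if d is None:
            return None
        days.append(d)
    return max(days)


def run_experiment_time_period(
    config: SimulationConfig,
    es0_bands: Sequence[str] = ("negative", "immune", "positive"),
    seeds: Iterable[int] = range(1, 31),
    stabilization_tol_frac: float = 0.02,
    stabilization_window: int = 3,
) -> ExperimentResult:
    """Experiment 1: contagion cycle over time for each initial S band."""
    seeds = _seed_list(seeds)
    if config.days < max(SNAPSHOT_DAYS):
        raise ValueError(f"horizon must cover the snapshot days {SNAPSHOT_DAYS}")
    cell_rows, snap_rows = [], []
    for band in es0_bands:
        cfg_band = config.with_(init=_replace_init(config.init, s_emotion=band))
        for seed in seeds:
            traj = run(cfg_band.with_(seed=seed))
            rec = traj.records
            stab = _count_stabilization_day(
                rec, config.n, stabilization_tol_frac, stabilization_window
            )
            final = rec.iloc[-1]
            cell_rows.append(
                {
                    "es0_band": band,
                    "seed": seed,
                    "stabilization_day": float(stab) if stab is not None else float("nan"),
                    "peak_negative_day": int(rec["n_negative"].idxmax()),
                    "final_prop_negative": final["n_negative"] / config.n,
                    "final_prop_immune": final["n_immune"] / config.n,
                    "final_prop_positive": final["n_positive"] / config.n,
                }
            )
            for t in SNAPSHOT_DAYS:
                row = rec.loc[rec["t"] == t].iloc[0].to_dict()
                row.update({"es0_band": band, "seed": seed})
                snap_rows.append(row)
    cells = pd.DataFrame(cell_rows)
    summary = (
        cells.groupby("es0_band", sort=False)
        .agg(
            median_stabilization_day=("stabilization_day", "median"),
            mean_final_prop_negative=("final_prop_negative", "mean"),
            mean_final_prop_immune=("final_prop_immune", "mean"),
            mean_final_prop_positive=("final_prop_positive", "mean"),
        )
        .reset_index()
    )
    return ExperimentResult(
        name="time_period",
        cells=cells,
        summary=summary,
        extras={"snapshots": pd.DataFrame(snap_rows)},
        meta={"seeds": seeds, "bands": list(es0_bands)},
    )


def _replace_init(init: InitSpec, **kwargs) -> InitSpec:
    return _dc_replace(init, **kwargs)


#: Majority-negative crowd used by Experiments 2 and 4: before refutation
#: takes hold most netizens sit below the immune/positive boundary.
NEGATIVE_CROWD = {"m_emotion": (0.0, 0.5)}


def run_experiment_intimacy(
    config: SimulationConfig,
    r_sr_levels: Sequence[float] = DEFAULT_LEVELS,
    horizon: int = 10,
    seeds: Iterable[int] = range(1, 31),
) -> ExperimentResult:
    """Experiment 2: pin R_sr to fixed intimacy levels and compare outcomes.

    Controlled design: the pinned level replaces w*b*a*v for every contact,
    the contagion-threshold gate is disabled (the level itself is the
    designed link strength), and the refutation source is maintained for the
    whole horizon.  The crowd starts majority-negative, as it does before
    refutation takes hold.
    """
    seeds = _seed_list(seeds)
    base = config.with_(
        days=horizon,
        init=_replace_init(config.init, **NEGATIVE_CROWD),
        transition=_dc_replace(
            config.transition, lambda_gate=0.0, spreader_active_days=horizon
        ),
    )
    cell_rows, count_rows = [], []
    for level in r_sr_levels:
        if not (0.0 <= level <= 1.0):
            raise ValueError(f"R_sr level must lie in [0, 1], got {level}")
        cfg = base.with_(r_sr_override=float(level))
        for seed in seeds:
            traj = run(cfg.with_(seed=seed))
            final = traj.records.iloc[-1]
            cell_rows.append(
                {
                    "r_sr": level,
                    "seed": seed,
                    "final_prop_negative": final["n_negative"] / config.n,
                    "final_prop_immune": final["n_immune"] / config.n,
                    "final_prop_positive": final["n_positive"] / config.n,
                    "final_n_s": final["n_s"],
                    "final_n_r": final["n_r"],
                    "final_n_m": final["n_m"],
                }
            )
            counts = traj.records[["t", "n_s", "n_r", "n_m"]].copy()
            counts["r_sr"] = level
            counts["seed"] = seed
            count_rows.append(counts)
    cells = pd.DataFrame(cell_rows)
    summary = (
        cells.groupby("r_sr", sort=False)
        .agg(
            mean_final_prop_negative=("final_prop_negative", "mean"),
            mean_final_prop_immune=("final_prop_immune", "mean"),
            mean_final_prop_positive=("final_prop_positive", "mean"),
        )
        .reset_index()
    )
    summary["mean_final_prop_positive_immune"] = (
        summary["mean_final_prop_positive"] + summary["mean_final_prop_immune"]
    )
    return ExperimentResult(
        name="intimacy",
        cells=cells,
        summary=summary,
        extras={"counts": pd.concat(count_rows, ignore_index=True)},
        meta={"seeds": seeds, "levels": list(r_sr_levels), "horizon": horizon},
    )


def run_experiment_speed_credibility(
    config: SimulationConfig,
    v_levels: Sequence[float] = DEFAULT_LEVELS,
    a_levels: Sequence[float] = DEFAULT_LEVELS,
    combos: Sequence[tuple[int, int]] = DEFAULT_COMBOS,
    horizon: int = 10,
    seeds: Iterable[int] = range(1, 31),
    stabilization_tol: float = 0.02,
    stabilization_window: int = 3,
) -> ExperimentResult:
    """Experiment 3: (v, a) grid; stabilized mean emotion of R-role agents.

    Controlled design: the netizen traits w and b are pinned to 1 so the
    transmission probability is exactly v*a, the contagion-threshold gate is
    disabled, and the refutation source is maintained for the whole horizon
    — isolating the authority's speed and credibility as the only varying
    factors.
    """
    seeds = _seed_list(seeds)
    if len(v_levels) != 3 or len(a_levels) != 3:
        raise ValueError("v_levels and a_levels must each provide three levels")
    base = config.with_(
        days=horizon,
        init=_replace_init(config.init, w_range=(1.0, 1.0), b_range=(1.0, 1.0)),
        transition=_dc_replace(
            config.transition, lambda_gate=0.0, spreader_active_days=horizon
        ),
    )
    cell_rows = []
    for vi, ai in combos:
        v, a = float(v_levels[vi - 1]), float(a_levels[ai - 1])
        cfg = base.with_(ctx=RefutationContext(a=a, v=v))
        for seed in seeds:
            traj = run(cfg.with_(seed=seed))
            er = stabilized_mean_emotion_r(
                traj, tol=stabilization_tol, window=stabilization_window
            )
            cell_rows.append(
                {
                    "combo": f"v{vi}*a{ai}",
                    "v_level": vi,
                    "a_level": ai,
                    "v": v,
                    "a": a,
                    "seed": seed,
                    "stabilized_mean_emotion_r": er,
                }
            )
    cells = pd.DataFrame(cell_rows)
    summary = (
        cells.groupby(["combo", "v_level", "a_level", "v", "a"], sort=False)
        .agg(stabilized_mean_emotion_r=("stabilized_mean_emotion_r", "mean"))
        .reset_index()
    )
    return ExperimentResult(
        name="speed_credibility",
        cells=cells,
        summary=summary,
        meta={
            "seeds": seeds,
            "v_levels": list(v_levels),
            "a_levels": list(a_levels),
            "combos": [list(c) for c in combos],
            "horizon": horizon,
        },
    )


def run_experiment_before_after(
    config: SimulationConfig,
    horizon: int = 10,
    seeds: Iterable[int] = range(1, 31),
    positive_range: tuple[float, float] = (0.66, 0.87),
) -> ExperimentResult:
    """Experiment 4: emotion distributions at the beginning vs the end of
    refutation, starting from a majority-negative crowd."""
    seeds = _seed_list(seeds)
    base = config.with_(
        days=horizon, init=_replace_init(config.init, **NEGATIVE_CROWD)
    )
    cell_rows, dist_rows = [], []
    lo, hi = positive_range
    for seed in seeds:
        traj = run(base.with_(seed=seed))
        first = traj.records.iloc[0]
        final = traj.records.iloc[-1]
        in_range = np.mean(
            (traj.final_emotions > lo) & (traj.final_emotions <= hi)
        )
        cell_rows.append(
            {
                "seed": seed,
                "initial_prop_negative": first["n_negative"] / config.n,
                "initial_prop_immune": first["n_immune"] / config.n,
                "initial_prop_positive": first["n_positive"] / config.n,
                "final_prop_negative": final["n_negative"] / config.n,
                "final_prop_immune": final["n_immune"] / config.n,
                "final_prop_positive": final["n_positive"] / config.n,
                "final_frac_in_066_087": float(in_range),
            }
        )
        dist_rows.append(
            pd.DataFrame(
                {
                    "seed": seed,
                    "stage": "initial",
                    "emotion": traj.initial_emotions,
                }
            )
        )
        dist_rows.append(
            pd.DataFrame(
                {"seed": seed, "stage": "final", "emotion": traj.final_emotions}
            )
        )
    cells = pd.DataFrame(cell_rows)
    summary = cells.drop(columns=["seed"]).mean().to_frame().T
    return ExperimentResult(
        name="before_after",
        cells=cells,
        summary=summary,
        extras={"distributions": pd.concat(dist_rows, ignore_index=True)},
        meta={"seeds": seeds, "horizon": horizon, "positive_range": [lo, hi]},
    )
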