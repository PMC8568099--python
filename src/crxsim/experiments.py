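"""In-silico experiment pipelines: clinical-vs-social dosing reach,
delivery-mode comparison, and information-sharing-propensity sweeps.

All pipelines run replicate simulations, flag the first two weeks as
burn-in and measure on week 3 (the window where behaviour has typically
stabilized). "Retained" referral knowledge means: an entry still present in
the agent's capped store at the window end, flagged as referral-derived,
with beta at or above a configurable floor (default 0: presence alone).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, replace

import pandas as pd

from .engine import RunResult, SimulationConfig, run
from .networks import build_network, degree_distribution
from .schedules import SchedulePool
from .world import World

__all__ = [
    "DosingReachResult",
    "ExperimentPlan",
    "classify_retainers",
    "dosing_reach_experiment",
    "delivery_mode_experiment",
    "pscore_sweep",
    "export_geography",
]

WEEK_HOURS = 168


@dataclass
class DosingReachResult:
    """Counts of agents reached by clinical vs social-only referral dosing.

    ``n_clinical``: agents who received >= 1 referral list before the
    window end and retain >= 1 referral-derived entry at the window end.
    ``n_social_only``: never clinically dosed but retaining such an entry.
    ``n_clinical_ever`` keeps the alternative denominator (all clinically
    dosed agents regardless of retention).
    """

    seed: int
    n_clinical: int
    n_social_only: int
    n_clinical_ever: int
    ratio: float | None  # n_social_only / n_clinical; None when undefined

    @property
    def ratio_vs_ever(self) -> float | None:
        return self.n_social_only / self.n_clinical_ever if self.n_clinical_ever else None


@dataclass
class ExperimentPlan:
    base_config: SimulationConfig
    n_replicates: int = 5
    measurement_window: tuple[int, int] = (2 * WEEK_HOURS, 3 * WEEK_HOURS)
    replicate_seed_stride: int = 101
    beta_floor: float = 0.0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.measurement_window[1] > self.base_config.n_days * 24:
            raise ValueError("measurement window exceeds the run horizon")

    def replicate_config(self, i: int) -> SimulationConfig:
        cfg = copy.deepcopy(self.base_config)
        cfg.seed = (self.base_config.seed + i * self.replicate_seed_stride) % (2**31)
        return cfg


def classify_retainers(result: RunResult, window: tuple[int, int],
                       beta_floor: float = 0.0) -> DosingReachResult:
    """Split agents into clinically dosed vs social-only retainers.

    Requires a knowledge snapshot at the window-end hour. The two sets are
    disjoint by construction; the ratio is None when no agent was
    clinically dosed.
    """
    end = window[1]
    if end not in result.snapshots:
        raise ValueError(
            f"run has no knowledge snapshot at hour {end}; have {sorted(result.snapshots)}"
        )
    snap = result.snapshots[end]
    retain_mask = snap["rx_derived"] & (snap["beta"] >= beta_floor)
    retainers = set(snap.loc[retain_mask, "agent_id"].unique())
    rx = result.healtherx_log
    clinical_ever = set(rx.loc[rx["hour"] < end, "agent_id"].unique())
    n_clin = len(retainers & clinical_ever)
    n_soc = len(retainers - clinical_ever)
    return DosingReachResult(
        seed=result.seed,
        n_clinical=n_clin,
        n_social_only=n_soc,
        n_clinical_ever=len(clinical_ever),
        ratio=(n_soc / n_clin) if n_clin else None,
    )


def _results_frame(rows: list[DosingReachResult], **extra) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seed": r.seed,
                "n_clinical": r.n_clinical,
                "n_social_only": r.n_social_only,
                "n_clinical_ever": r.n_clinical_ever,
                "ratio": r.ratio,
                "ratio_vs_ever": r.ratio_vs_ever,
                **extra,
            }
            for r in rows
        ]
    )


def dosing_reach_experiment(world: World, pool: SchedulePool,
                            plan: ExperimentPlan) -> tuple[pd.DataFrame, dict]:
    """Replicate runs measuring the social-vs-clinical dosing reach ratio.

    Returns (per-run table, summary with mean and range of the ratio).
    """
    rows = []
    for i in range(plan.n_replicates):
        res = run(world, pool, plan.replicate_config(i))
        rows.append(classify_retainers(res, plan.measurement_window, plan.beta_floor))
        del res
    table = _results_frame(rows)
    ratios = table["ratio"].dropna()
    summary = {
        "n_replicates": plan.n_replicates,
        "mean_ratio": float(ratios.mean()) if len(ratios) else None,
        "min_ratio": float(ratios.min()) if len(ratios) else None,
        "max_ratio": float(ratios.max()) if len(ratios) else None,
        "mean_n_clinical": float(table["n_clinical"].mean()),
        "mean_n_social_only": float(table["n_social_only"].mean()),
    }
    return table, summary


def delivery_mode_experiment(world: World, pool: SchedulePool, plan: ExperimentPlan,
                             modes: tuple[str, ...] = ("physician", "nurse", "clerk"),
                             ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Replicates per delivery mode; per-mode reach summaries.

    Returns (per-run table, per-mode summary table, descriptive statistics
    including a Kruskal-Wallis rank test of n_social_only across modes —
    reported descriptively, not as a confirmatory test).
    """
    all_rows = []
    for mode in modes:
        for i in range(plan.n_replicates):
            cfg = plan.replicate_config(i)
            cfg.delivery = replace(cfg.delivery, delivery_mode=mode)
            res = run(world, pool, cfg)
            r = classify_retainers(res, plan.measurement_window, plan.beta_floor)
            all_rows.append((mode, r))
            del res
    table = pd.concat(
        [_results_frame([r], mode=m) for m, r in all_rows], ignore_index=True
    )
    per_mode = table.groupby("mode").agg(
        mean_social_only=("n_social_only", "mean"),
        sd_social_only=("n_social_only", "std"),
        mean_clinical=("n_clinical", "mean"),
        mean_ratio=("ratio", "mean"),
    )
    stats: dict = {}
    if len(modes) > 1 and plan.n_replicates > 1:
        from scipy.stats import kruskal

        groups = [table.loc[table["mode"] == m, "n_social_only"].to_numpy() for m in modes]
        try:
            h, p = kruskal(*groups)
            stats = {"kruskal_H": float(h), "kruskal_p": float(p)}
        except ValueError:  # all values identical
            stats = {"kruskal_H": 0.0, "kruskal_p": 1.0}
    return table, per_mode, stats


def pscore_sweep(world: World, pool: SchedulePool, plan: ExperimentPlan,
                 multipliers: dict[str, float] | list[float],
                 ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run the simulation at several sharing-propensity levels.

    ``multipliers`` scales the pool's low/medium/high rates (clipped to
    [0, 1]); for each level the week-3 exchange network's degree
    distribution is computed. Returns (per-level summary table, level ->
    degree distribution).
    """
    if isinstance(multipliers, list):
        multipliers = {f"x{m:g}": m for m in multipliers}
    if any(m < 0 for m in multipliers.values()):
        raise ValueError("multipliers must be non-negative")
    rows = []
    dists: dict[str, pd.DataFrame] = {}
    for level, mult in multipliers.items():
        scaled = {
            k: min(1.0, v * mult) if k != "none" else 0.0
            for k, v in pool.p_rates.items()
        }
        level_pool = SchedulePool(catalog=pool.catalog, templates=pool.templates,
                                  p_rates=scaled)
        deg_levels = []
        for i in range(plan.n_replicates):
            res = run(world, level_pool, plan.replicate_config(i))
            net = build_network(res.events_exchange, plan.measurement_window)
            deg = net.total_degrees()
            s = net.summary()
            rows.append(
                {
                    "level": level,
                    "multiplier": mult,
                    "seed": res.seed,
                    "n_nodes": s.n_nodes,
                    "n_edges": s.n_edges,
                    "mean_total_degree": s.mean_degree,
                    "max_total_degree": s.max_degree,
                }
            )
            deg_levels.append(degree_distribution(net))
            del res
        merged = (
            pd.concat(deg_levels).groupby("degree", as_index=False)["n_nodes"].sum()
            if deg_levels
            else pd.DataFrame(columns=["degree", "n_nodes"])
        )
        dists[level] = merged
    return pd.DataFrame(rows), dists


def export_geography(result: RunResult, window: tuple[int, int], world: World,
                     out_csv=None, out_geojson=None,
                     beta_floor: float = 0.0) -> pd.DataFrame:
    """Home coordinates of clinical vs social-only retainers.

    Returns a point table (agent_id, x, y, dosing: clinical|social_only);
    optionally writes CSV and GeoJSON for external mapping.
    """
    end = window[1]
    snap = result.snapshots[end]
    retain = snap.loc[snap["rx_derived"] & (snap["beta"] >= beta_floor), "agent_id"].unique()
    rx = result.healtherx_log
    clinical = set(rx.loc[rx["hour"] < end, "agent_id"].unique())
    homes = world.agents.set_index("agent_id")["household_id"]
    coords = world.places.set_index("place_id")[["x", "y"]]
    rows = []
    for a in sorted(retain):
        xy = coords.loc[int(homes.loc[a])]
        rows.append(
            {
                "agent_id": int(a),
                "x": float(xy["x"]),
                "y": float(xy["y"]),
                "dosing": "clinical" if a in clinical else "social_only",
            }
        )
    table = pd.DataFrame(rows, columns=["agent_id", "x", "y", "dosing"])
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if out_geojson is not None:
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [r["x"], r["y"]]},
                    "properties": {"agent_id": r["agent_id"], "dosing": r["dosing"]},
                }
                for _, r in table.iterrows()
            ],
        }
        with open(out_geojson, "w") as fh:
            json.dump(fc, fh)
    return table
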