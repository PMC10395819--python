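"""End-to-end monthly analysis: raw fixes to scaling exponents and test grids.

The analysis unit is one individual in one UTC calendar month. For each unit
the pipeline detects stops, clusters them into stay-regions, builds the NTB
and NP symbolic sequences, and computes the mobility metrics. Per month it
then fits the collective exponents ζ (Zipf visitation decay) and μ
(exploration growth) on population-averaged curves for both schemes, and
summarises top-rank visitation frequencies and mean stay-region counts.
Finally it runs the group significance grid (breeding vs non-breeding,
female vs male, and study population vs an optional comparison population).

Defaults mirror the published gull analysis: δ = 150 m, τ = 18 min,
ϵ = 400 m (200 m for the human-style comparison data), 1-hour bins,
breeding window April-June.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import group_stats, mobility_metrics, temporal_aggregation, trajectory_io
from .stay_regions import ClusteringParams, ClusterReport, cluster_stops
from .stop_detection import StopDetectionParams, detect_stops, stops_to_frame
from .trajectory_io import ReadReport, Trajectory

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    input_csv: str
    output_dir: str
    column_map: dict | None = None
    timestamp_format: str | None = None
    delta_m: float = 150.0
    tau_min: float = 18.0
    eps_m: float = 400.0
    min_stops: int = 2
    keep_singletons: bool = False
    bin_width_hours: float = 1.0
    breeding_months: set[int] = field(default_factory=lambda: {4, 5, 6})
    sex_map: dict[str, str] | None = None  # individual id -> "female" | "male"
    comparison_csv: str | None = None  # optional second population
    comparison_eps_m: float = 200.0
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "breeding_months" in raw:
        raw["breeding_months"] = set(raw["breeding_months"])
    return RunConfig(**raw)


@dataclass
class PipelineResult:
    """Bundle of all result tables from one run."""

    stops: pd.DataFrame
    regions: pd.DataFrame
    visits: pd.DataFrame
    sequences: pd.DataFrame
    metrics: pd.DataFrame
    exponents: pd.DataFrame
    top_rank_fr: pd.DataFrame
    region_counts: pd.DataFrame
    significance: pd.DataFrame
    log: dict


def _process_dataset(
    trajectories: list[Trajectory], config: RunConfig, eps_m: float
) -> tuple[dict, pd.DataFrame, dict]:
    """Per-(individual, month) stops/regions/sequences/metrics for one dataset.

    Returns (units, metrics frame, accounting). ``units`` maps
    (id, year, month) to a dict with stops, regions, visits and sequences.
    """
    stop_params = StopDetectionParams(config.delta_m, config.tau_min)
    clus_params = ClusteringParams(
        eps_m=eps_m,
        min_stops=config.min_stops,
        keep_singletons=config.keep_singletons,
    )
    bin_width = pd.Timedelta(hours=config.bin_width_hours)

    units: dict = {}
    metric_rows = []
    accounting = {"n_stops": 0, "n_noise_stops": 0, "n_units": 0}
    for traj in trajectories:
        for (year, month), sub in trajectory_io.split_by_month(traj).items():
            stops = detect_stops(sub, stop_params)
            accounting["n_stops"] += len(stops)
            if not stops:
                continue
            rep = ClusterReport()
            regions, visits = cluster_stops(stops, clus_params, report=rep)
            accounting["n_noise_stops"] += rep.n_noise
            if not visits:
                continue
            seq_ntb = temporal_aggregation.aggregate_ntb(visits, bin_width=bin_width)
            seq_np = temporal_aggregation.aggregate_np(visits)
            units[(traj.individual_id, year, month)] = {
                "stops": stops,
                "regions": regions,
                "visits": visits,
                "ntb": seq_ntb,
                "np": seq_np,
            }
            accounting["n_units"] += 1
            for scheme, seq in (("ntb", seq_ntb), ("np", seq_np)):
                rank = mobility_metrics.visitation_frequency(seq)
                growth = mobility_metrics.distinct_over_time(seq)
                r_g = mobility_metrics.sequence_radius_of_gyration(seq, regions)
                metric_rows.append(
                    {
                        "id": traj.individual_id,
                        "year": year,
                        "month": month,
                        "scheme": scheme,
                        "r_g_m": r_g,
                        "f_1": rank.frequencies[0],
                        "f_2": rank.frequencies[1] if len(rank.frequencies) > 1 else np.nan,
                        "s_total": int(growth.counts[-1]),
                        "n_visits": len(seq.non_gap_symbols),
                        "seq_len": len(seq),
                    }
                )
    metrics = pd.DataFrame(
        metric_rows,
        columns=[
            "id", "year", "month", "scheme", "r_g_m", "f_1", "f_2",
            "s_total", "n_visits", "seq_len",
        ],
    ).sort_values(["id", "year", "month", "scheme"], ignore_index=True)
    return units, metrics, accounting


def _monthly_exponents(units: dict) -> pd.DataFrame:
    """ζ and μ per month and scheme, fitted on population-averaged curves."""
    rows = []
    months = sorted({(y, m) for (_, y, m) in units})
    for year, month in months:
        for scheme in ("ntb", "np"):
            seqs = [u[scheme] for k, u in units.items() if k[1:] == (year, month)]
            rank_curves = [mobility_metrics.visitation_frequency(s) for s in seqs]
            growth_curves = [mobility_metrics.distinct_over_time(s) for s in seqs]
            row = {"year": year, "month": month, "scheme": scheme,
                   "n_individuals": len(seqs)}
            for name, curves in (("zeta", rank_curves), ("mu", growth_curves)):
                avg = mobility_metrics.population_curve(curves)
                try:
                    fit = mobility_metrics.fit_exponent(avg.x, avg.mean_y)
                    row[name] = fit.exponent
                    row[f"{name}_r2"] = fit.r_squared
                    row[f"{name}_n_points"] = fit.n_points
                except ValueError:
                    row[name] = np.nan
                    row[f"{name}_r2"] = np.nan
                    row[f"{name}_n_points"] = 0
            rows.append(row)
    return pd.DataFrame(rows)


METRIC_COLUMNS = {"f_r": "f_1", "r_g": "r_g_m", "S(t)": "s_total"}


def _significance_grid(
    metrics: pd.DataFrame,
    breeding_months: set[int],
    sex_map: dict[str, str] | None,
    comparison_metrics: pd.DataFrame | None,
) -> pd.DataFrame:
    """Breeding/sex/population significance grid over metrics and schemes.

    Observations are per-individual-month metric values: top-rank visitation
    frequency for f_r, the monthly radius of gyration for r_g, and the
    terminal distinct-region count for S(t).
    """
    rows = []
    for grouping in ("breeding vs non-breeding", "male vs female", "study vs comparison"):
        for metric, col in METRIC_COLUMNS.items():
            for scheme in ("np", "ntb"):
                sub = metrics[metrics["scheme"] == scheme]
                if grouping == "breeding vs non-breeding":
                    a = sub[sub["month"].isin(breeding_months)][col].dropna().tolist()
                    b = sub[~sub["month"].isin(breeding_months)][col].dropna().tolist()
                    labels = ("breeding", "non-breeding")
                elif grouping == "male vs female":
                    if sex_map:
                        sexes = sub["id"].map(sex_map)
                        a = sub[sexes == "male"][col].dropna().tolist()
                        b = sub[sexes == "female"][col].dropna().tolist()
                    else:
                        a, b = [], []
                    labels = ("male", "female")
                else:
                    a = sub[col].dropna().tolist()
                    if comparison_metrics is not None:
                        csub = comparison_metrics[comparison_metrics["scheme"] == scheme]
                        b = csub[col].dropna().tolist()
                    else:
                        b = []
                    labels = ("study", "comparison")
                cmp = group_stats.compare_groups(
                    a, b, metric=metric, scheme=scheme, labels=labels
                )
                rows.append(
                    {
                        "grouping": grouping,
                        "metric": metric,
                        "scheme": scheme.upper(),
                        "n_a": len(a),
                        "n_b": len(b),
                        "testable": cmp.testable,
                        "p_ks": cmp.p_ks,
                        "p_kw": cmp.p_kw,
                        "ks_mark": group_stats.significance_mark(cmp.p_ks),
                        "kw_mark": group_stats.significance_mark(cmp.p_kw),
                    }
                )
    return pd.DataFrame(rows)


def _units_frames(units: dict):
    """Flatten per-unit artifacts into stops/regions/visits/sequences frames."""
    stop_frames, region_rows, visit_rows, seq_frames = [], [], [], []
    for (ind, year, month), u in sorted(units.items()):
        sf = stops_to_frame(u["stops"])
        sf.insert(1, "year", year)
        sf.insert(2, "month", month)
        stop_frames.append(sf)
        for r in u["regions"]:
            region_rows.append(
                {
                    "id": ind, "year": year, "month": month,
                    "region_id": r.region_id,
                    "centroid_lon": r.centroid_lon,
                    "centroid_lat": r.centroid_lat,
                    "n_stops": r.n_stops,
                }
            )
        for v in u["visits"]:
            visit_rows.append(
                {
                    "id": ind, "year": year, "month": month,
                    "region_id": v.region_id,
                    "t_start": v.t_start, "t_end": v.t_end,
                }
            )
        for scheme in ("ntb", "np"):
            f = u[scheme].to_frame()
            f.insert(1, "year", year)
            f.insert(2, "month", month)
            seq_frames.append(f)
    stops = pd.concat(stop_frames, ignore_index=True) if stop_frames else pd.DataFrame()
    regions = pd.DataFrame(region_rows)
    visits = pd.DataFrame(visit_rows)
    sequences = pd.concat(seq_frames, ignore_index=True) if seq_frames else pd.DataFrame()
    return stops, regions, visits, sequences


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full monthly analysis and write all result tables.

    Deterministic for a given config: rerunning writes byte-identical tables.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        read_rep = ReadReport()
        trajectories = trajectory_io.read_fixes(
            config.input_csv,
            column_map=config.column_map,
            timestamp_format=config.timestamp_format,
            report=read_rep,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("read", str(e)) from e
    if not trajectories:
        raise PipelineError("read", f"no valid fixes in {config.input_csv}")

    try:
        units, metrics, accounting = _process_dataset(
            trajectories, config, eps_m=config.eps_m
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("process", str(e)) from e
    if not units:
        raise PipelineError("process", "no analysable individual-months")

    comparison_metrics = None
    comp_accounting = None
    if config.comparison_csv:
        try:
            comp_traj = trajectory_io.read_fixes(
                config.comparison_csv,
                column_map=config.column_map,
                timestamp_format=config.timestamp_format,
            )
            _, comparison_metrics, comp_accounting = _process_dataset(
                comp_traj, config, eps_m=config.comparison_eps_m
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("comparison", str(e)) from e

    try:
        exponents = _monthly_exponents(units)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("exponents", str(e)) from e

    # Fig-7-shaped summary: mean top-1 / top-2 visitation frequency per month
    top_rank_fr = (
        metrics.groupby(["year", "month", "scheme"])[["f_1", "f_2"]]
        .mean()
        .reset_index()
    )
    # Fig-8-shaped summary: mean distinct stay-region count per month
    region_counts = (
        metrics[metrics["scheme"] == "np"]
        .groupby(["year", "month"])["s_total"]
        .mean()
        .rename("mean_n_regions")
        .reset_index()
    )

    try:
        significance = _significance_grid(
            metrics, config.breeding_months, config.sex_map, comparison_metrics
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("group_stats", str(e)) from e

    stops, regions, visits, sequences = _units_frames(units)
    log = {
        "config": {
            k: (sorted(v) if isinstance(v, set) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "read": dataclasses.asdict(read_rep),
        "accounting": accounting,
        "comparison_accounting": comp_accounting,
    }

    result = PipelineResult(
        stops=stops, regions=regions, visits=visits, sequences=sequences,
        metrics=metrics, exponents=exponents, top_rank_fr=top_rank_fr,
        region_counts=region_counts, significance=significance, log=log,
    )
    _write_result(result, out_dir)
    return result


def _write_result(result: PipelineResult, out_dir: Path) -> None:
    fmt = "%.10g"
    tables = {
        "stops.csv": result.stops,
        "regions.csv": result.regions,
        "visits.csv": result.visits,
        "sequences.csv": result.sequences,
        "metrics.csv": result.metrics,
        "exponents.csv": result.exponents,
        "top_rank_fr.csv": result.top_rank_fr,
        "region_counts.csv": result.region_counts,
        "significance.csv": result.significance,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / name, index=False, float_format=fmt)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2, sort_keys=True, default=str)
    # human-readable significance grid (✓ <0.05, * <0.1, — otherwise)
    lines = ["| grouping | metric | scheme | KS | KW |", "|---|---|---|---|---|"]
    for _, row in result.significance.iterrows():
        lines.append(
            f"| {row['grouping']} | {row['metric']} | {row['scheme']} "
            f"| {row['ks_mark']} | {row['kw_mark']} |"
        )
    (out_dir / "significance.md").write_text("\n".join(lines) + "\n")
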