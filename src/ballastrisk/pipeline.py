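"""End-to-end orchestration: match -> profiles -> normalisation -> paired
distances -> difference categories -> regional tests -> seasonal summaries.

Every stage's record counts are reconciled in a :class:`RunManifest`
(input = retained + excluded), because the analysis' silent-failure risk
is in its filters: inland ports dropped by the matcher, records whose
ports lack profiles, and missing grid cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .data_io import (
    EnvGridStack,
    PortRegistry,
    TankRecord,
    load_env_grid,
    load_ports,
    load_tank_records,
    profiles_to_frame,
    save_profiles,
)
from .env_distance import (
    DEFAULT_RISK_THRESHOLDS,
    MonthlyVectorMode,
    RiskThresholds,
    fit_annual_norm,
    fit_monthly_norm,
    risk_category,
)
from .errors import PipelineError
from .grid_matching import DEFAULT_MAX_CELLS, build_profiles
from .seasonal_cycle import port_stats_table, region_month_means, summarize_port_pairs
from .temporal_comparison import (
    DEFAULT_DIFF_THRESHOLDS,
    DiffThresholds,
    diff_thresholds_from_data,
    histogram_table,
    pair_distances,
    per_port_average_diff,
    regional_comparison,
)

log = logging.getLogger("ballastrisk")


@dataclass
class StageCounts:
    stage: str
    n_input: int
    n_retained: int
    n_excluded: int

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + self.n_excluded


@dataclass
class RunManifest:
    """Reproducibility record of one full analysis run."""

    version: str
    seed: int | None
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[StageCounts] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def add_stage(self, stage: str, n_input: int, n_retained: int) -> None:
        sc = StageCounts(stage, n_input, n_retained, n_input - n_retained)
        if not sc.reconciles():
            raise PipelineError(f"stage {stage}: counts do not reconcile")
        self.stages.append(sc)
        log.info("%s: %d in, %d retained, %d excluded", stage, sc.n_input, sc.n_retained, sc.n_excluded)

    def reconciles(self) -> bool:
        return all(s.reconciles() for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "input_digests": self.input_digests,
            "stages": [vars(s) for s in self.stages],
            "outputs": self.outputs,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """In-memory results of a full run (the CSVs' DataFrame counterparts)."""

    manifest: RunManifest
    profiles_frame: pd.DataFrame
    match_report: pd.DataFrame
    pairs: pd.DataFrame
    per_port: pd.DataFrame
    region_tests: pd.DataFrame
    port_stats: pd.DataFrame
    pair_summaries: pd.DataFrame
    region_months: pd.DataFrame
    diff_thresholds: DiffThresholds


def run_full_analysis(
    ports: PortRegistry,
    stack: EnvGridStack,
    records: Sequence[TankRecord],
    out_dir: str | Path | None = None,
    max_cells: float = DEFAULT_MAX_CELLS,
    risk_thresholds: RiskThresholds = DEFAULT_RISK_THRESHOLDS,
    diff_threshold_mode: str = "published",
    monthly_mode: MonthlyVectorMode = "four_slot",
    monthly_norm_source: str = "pooled",
    alpha: float = 0.05,
    k_bins: int = 5,
    seed: int | None = None,
    config_snapshot: dict | None = None,
) -> AnalysisResult:
    """Execute every analysis stage on in-memory inputs.

    ``diff_threshold_mode`` selects the difference-category cutoffs:
    "published" uses the default calibration, "data" recalibrates the
    75/90th percentiles from this run's own differences.

    ``monthly_norm_source`` chooses how monthly vectors are z-scored:
    "pooled" (default) fits on the pooled port-by-month population;
    "annual" reuses the annual normalisation parameters, under which
    monthly and annual distances coincide exactly for ports without
    seasonality (only meaningful in the four-slot monthly mode).

    When ``out_dir`` is given all result tables are written as CSV along
    with the run manifest.
    """
    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config=dict(
            config_snapshot or {},
            max_cells=max_cells,
            diff_threshold_mode=diff_threshold_mode,
            monthly_mode=monthly_mode,
            monthly_norm_source=monthly_norm_source,
            alpha=alpha,
            k_bins=k_bins,
        ),
    )

    # 1. match ports to the climatology
    profiles, match_report = build_profiles(ports, stack, max_cells=max_cells)
    manifest.add_stage("grid_matching", len(ports), len(profiles))
    prof_map = {p.port_id: p for p in profiles}

    # 2. normalisation parameters on the matched reference population
    annual_norm = fit_annual_norm(profiles)
    if monthly_norm_source == "annual":
        if monthly_mode != "four_slot":
            raise PipelineError(
                "monthly_norm_source='annual' requires the four-slot monthly mode"
            )
        monthly_norm = annual_norm
    else:
        monthly_norm = fit_monthly_norm(profiles, monthly_mode)

    # 3. paired monthly/annual distances per tank record
    coasts = {p.port_id: p.coast for p in ports if p.coast}
    pairs, skipped = pair_distances(
        records, prof_map, annual_norm, monthly_norm, monthly_mode, coasts
    )
    manifest.add_stage("pair_distances", len(records), len(pairs))
    if pairs.empty:
        raise PipelineError("no tank record could be paired with profiles")
    pairs["risk_annual"] = [risk_category(d, risk_thresholds) for d in pairs["d_annual"]]
    pairs["risk_month"] = [risk_category(d, risk_thresholds) for d in pairs["d_month"]]

    # 4. difference categories and per-port averages
    if diff_threshold_mode == "data":
        dthr = diff_thresholds_from_data(pairs["diff"])
    else:
        dthr = DEFAULT_DIFF_THRESHOLDS
    per_port = per_port_average_diff(pairs, dthr)

    # 5. regional Wilcoxon comparison per year
    region_tests = regional_comparison(pairs, alpha=alpha)

    # 6. seasonal variability: per-port STDEVs and cycled route analysis
    port_stats = port_stats_table(profiles, k_bins=k_bins)
    regions = {p.port_id: p.region for p in ports}
    retained = [r for r in records if r.source_port_id in prof_map and r.dest_port_id in prof_map]
    pair_summaries = summarize_port_pairs(
        retained, prof_map, monthly_norm, regions, monthly_mode
    )
    region_months = region_month_means(pair_summaries)

    result = AnalysisResult(
        manifest=manifest,
        profiles_frame=profiles_to_frame(profiles),
        match_report=match_report,
        pairs=pairs,
        per_port=per_port,
        region_tests=region_tests,
        port_stats=port_stats,
        pair_summaries=pair_summaries,
        region_months=region_months,
        diff_thresholds=dthr,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "profiles": result.profiles_frame,
            "match_report": match_report,
            "distance_pairs": pairs,
            "per_port_diffs": per_port,
            "region_tests": region_tests,
            "port_stats": port_stats,
            "pair_summaries": pair_summaries,
            "region_month_means": region_months,
            "diff_histogram": histogram_table(pairs["diff"]),
        }
        for name, df in tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            manifest.outputs[name] = path.name
        manifest.write(out / "manifest.json")
    return result


def run_from_files(
    ports_path: str | Path,
    grid_temperature_path: str | Path,
    grid_salinity_path: str | Path,
    tanks_path: str | Path,
    out_dir: str | Path,
    **kwargs,
) -> AnalysisResult:
    """File-based entry point: load the three inputs, run, write outputs."""
    ports = load_ports(ports_path)
    stack = EnvGridStack(
        temperature=load_env_grid(grid_temperature_path, "temperature"),
        salinity=load_env_grid(grid_salinity_path, "salinity"),
    )
    records, report = load_tank_records(tanks_path, ports)
    result = run_full_analysis(ports, stack, records, out_dir=out_dir, **kwargs)
    result.manifest.input_digests = {
        "ports": _digest(ports_path),
        "grid_temperature": _digest(grid_temperature_path),
        "grid_salinity": _digest(grid_salinity_path),
        "tank_records": _digest(tanks_path),
    }
    stages = result.manifest.stages
    stages.insert(0, StageCounts("load_tank_records", report.n_input, report.n_retained, report.n_dropped))
    result.manifest.write(Path(out_dir) / "manifest.json")
    return result
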