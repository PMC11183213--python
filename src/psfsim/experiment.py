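"""Factorial experiment orchestration: scenarios x invasion arms x replicates.

The full design crosses all 38 PSFI scenarios with and without an invasion
event (76 simulation scenarios); at 100 replicates that is 7,600 runs.
Desk-scale suites use the same machinery with fewer replicates.  Replicate
``r`` (0-based) of any scenario/arm batch uses seed ``base_seed + r``, so
batches are reproducible and replicate streams are paired across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .engine import SimConfig, SimulationResult, run_simulation
from .metrics import (
    bray_curtis_change,
    community_avg_growth_rate,
    invader_percent_biomass,
    inverse_simpson,
)
from .networks import ScenarioSpec, build_scenario_table, enumerate_scenarios

__all__ = [
    "RunSpec",
    "ExperimentPlan",
    "build_full_plan",
    "replicate_metrics",
    "run_plan",
    "scenario_summary",
    "invasibility_ordering",
    "DOMINANCE_THRESHOLD_PCT",
]

DOMINANCE_THRESHOLD_PCT = 10.0

METRIC_COLUMNS = [
    "invader_pct_final",
    "inv_simpson_10000",
    "inv_simpson_count_10000",
    "bray_curtis_5000_10000",
    "avg_growth_rate_10000",
]


@dataclass(frozen=True)
class RunSpec:
    """One planned simulation: a scenario arm plus its replicate seed."""

    scenario: ScenarioSpec
    replicate: int
    seed: int

    @property
    def run_id(self) -> str:
        arm = "inv" if self.scenario.invasion else "noinv"
        return f"{self.scenario.name}_{arm}_r{self.replicate:03d}"


@dataclass
class ExperimentPlan:
    """A deterministic batch of runs over scenarios, arms and replicates."""

    scenarios: Sequence[ScenarioSpec]
    invasion_arms: tuple[bool, ...] = (True, False)
    n_replicates: int = 100
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_runs(self) -> int:
        return len(self.scenarios) * len(self.invasion_arms) * self.n_replicates

    def runs(self) -> Iterator[RunSpec]:
        for scenario in self.scenarios:
            for invasion in self.invasion_arms:
                for r in range(self.n_replicates):
                    yield RunSpec(
                        scenario=scenario.with_invasion(invasion),
                        replicate=r,
                        seed=self.base_seed + r,
                    )


def build_full_plan(n_replicates: int = 100, base_seed: int = 1) -> ExperimentPlan:
    """The complete factorial: 38 scenarios x 2 invasion arms x replicates."""
    return ExperimentPlan(
        scenarios=enumerate_scenarios(),
        invasion_arms=(True, False),
        n_replicates=n_replicates,
        base_seed=base_seed,
    )


def replicate_metrics(result: SimulationResult) -> dict:
    """Standard per-replicate metric row from one simulation.

    Pre-invasion metrics use the step-10,000 (diversity, average growth
    rate) and step-5,000 (compositional change baseline) records;
    invasibility is the invader's biomass share at the final step.
    """
    table = build_scenario_table(
        result.scenario, result.config.n_resident_species, result.config.rates
    )
    pre = result.summary_at(10_000) if 10_000 in result.steps else None
    mid = result.summary_at(5_000) if 5_000 in result.steps else None
    row = {
        "scenario": result.scenario.name,
        "invasion": result.scenario.invasion,
        "seed": result.config.rng_seed,
        "invader_pct_final": invader_percent_biomass(result.final),
        "inv_simpson_10000": np.nan,
        "inv_simpson_count_10000": np.nan,
        "bray_curtis_5000_10000": np.nan,
        "avg_growth_rate_10000": np.nan,
    }
    if pre is not None:
        row["inv_simpson_10000"] = inverse_simpson(pre, basis="biomass")
        row["inv_simpson_count_10000"] = inverse_simpson(pre, basis="abundance")
        row["avg_growth_rate_10000"] = community_avg_growth_rate(pre, table)
        if mid is not None:
            row["bray_curtis_5000_10000"] = bray_curtis_change(mid, pre)
    return row


def run_plan(
    plan: ExperimentPlan,
    config: SimConfig | None = None,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute every run of a plan and return the per-replicate metrics table.

    With ``out_dir`` each completed run is persisted as
    ``<run_id>.json`` beside a resolved-plan manifest; runs whose file
    already exists are loaded instead of recomputed, so an interrupted
    batch resumes where it stopped.
    """
    config = config or SimConfig()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in plan.runs():
        row_file = (
            out_path / f"{spec.run_id}.json" if out_path is not None else None
        )
        if row_file is not None and row_file.exists():
            row = pd.read_json(row_file, typ="series").to_dict()
        else:
            cfg = _with_seed(config, spec.seed)
            try:
                result = run_simulation(spec.scenario, cfg)
            except Exception as exc:  # keep the batch alive
                rows.append(
                    {"scenario": spec.scenario.name,
                     "invasion": spec.scenario.invasion,
                     "replicate": spec.replicate, "seed": spec.seed,
                     "error": str(exc)}
                )
                continue
            row = replicate_metrics(result)
            row["replicate"] = spec.replicate
            if row_file is not None:
                pd.Series(row).to_json(row_file)
        if progress:
            print(f"{spec.run_id}: invader {row['invader_pct_final']:.2f}%")
        rows.append(row)
    return pd.DataFrame(rows)


def _with_seed(config: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace

    return replace(config, rng_seed=seed)


def scenario_summary(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Scenario-level means with normal-approximation 95% confidence
    intervals (mean +/- 1.96 SE over replicates) for every metric column."""
    records = []
    for (scenario, invasion), grp in per_replicate.groupby(
        ["scenario", "invasion"], sort=False
    ):
        rec = {"scenario": scenario, "invasion": invasion, "n": len(grp)}
        for col in METRIC_COLUMNS:
            if col not in grp:
                continue
            x = grp[col].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            mean = x.mean()
            se = x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0
            rec[f"{col}_mean"] = mean
            rec[f"{col}_ci_lo"] = mean - 1.96 * se
            rec[f"{col}_ci_hi"] = mean + 1.96 * se
        records.append(rec)
    return pd.DataFrame(records)


def invasibility_ordering(summary: pd.DataFrame) -> pd.DataFrame:
    """Rank invasion-arm scenarios by mean final invader biomass share and
    flag dominance (mean > 10% of total biomass)."""
    inv = summary[summary["invasion"]].copy()
    inv = inv.sort_values("invader_pct_final_mean", ascending=False)
    inv["rank"] = np.arange(1, len(inv) + 1)
    inv["dominant"] = inv["invader_pct_final_mean"] > DOMINANCE_THRESHOLD_PCT
    return inv.reset_index(drop=True)
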