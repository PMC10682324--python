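"""End-to-end drivers: pool -> scenarios -> break-even grid -> report.

Two run styles are supported.  A *replication* run (the default) takes
the published pooled reading times and scenario saved times as inputs,
because the original pooling weights are unstated and the printed values
cannot be re-derived exactly; it reproduces the published break-even
table up to a documented set of last-decimal discrepancies.  A
*recomputation* run pools the corpus itself (unweighted by default) and
derives the scenarios from the scenario rule, carrying full precision
throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .corpus import Locator, PricingKind, Settings, load_corpus, load_settings
from .economics import (
    BreakEvenResult,
    SavedTimeRow,
    breakeven_curve,
    evaluate_grid,
    per_case_cost,
)
from .pooling import (
    Arm,
    MultiReaderPolicy,
    PooledEstimate,
    PoolingMethod,
    pool_reading_times,
    summarize_second_reader,
)
from .report import (
    Discrepancy,
    compare_to_snapshot,
    pooled_table,
    render_fig1,
    render_table2,
)
from .scenarios import ScenarioLabel, derive_scenarios


class ConsistencyError(RuntimeError):
    """An internal cross-check (W*C=P, monotonicity, ordering) failed."""


class RunConfig(BaseModel):
    """Configuration for a pipeline run."""

    corpus: str = "table1"
    settings: str = "default"
    method: PoolingMethod = PoolingMethod.UNWEIGHTED
    multi_reader_policy: MultiReaderPolicy = MultiReaderPolicy.AVERAGE_WITHIN_STUDY
    replication: bool = True
    use_printed_salaries: bool = True
    include_second_reader: bool = True
    saved_time_grid: tuple[float, float, float] = (10.0, 180.0, 5.0)  # lo, hi, step
    output_dir: Optional[str] = None
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All outputs of a break-even run, with their unrounded sources."""

    pooled: dict[str, PooledEstimate]
    second_reader_range_s: tuple[float, float]
    scenario_table: pd.DataFrame
    results: list[BreakEvenResult]
    table2: pd.DataFrame
    discrepancies: list[Discrepancy]
    curves: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def run_pool(config: RunConfig | None = None) -> tuple[dict[str, PooledEstimate], pd.DataFrame]:
    """Pool every arm of the corpus; optionally write the pooling report CSV."""
    config = config or RunConfig()
    corpus = load_corpus(config.corpus)
    pooled = {
        arm.value: pool_reading_times(corpus, arm, config.method, config.multi_reader_policy)
        for arm in Arm
    }
    table = pooled_table(pooled)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "pooled.csv", index=False)
    return pooled, table


def _saved_time_rows(
    config: RunConfig, settings: Settings, pooled: dict[str, PooledEstimate]
) -> list[SavedTimeRow]:
    if config.replication:
        printed = settings.printed_pooled["saved_time_concurrent"]
        concurrent = SavedTimeRow(
            label="concurrent_reader",
            saved_time_s=printed.mean,
            saved_time_ci=(printed.ci_lo, printed.ci_hi),
        )
        scen_rows = [
            SavedTimeRow(
                label=f"prescreen_{label}",
                saved_time_s=settings.printed_scenarios[label].mean,
                saved_time_ci=(
                    settings.printed_scenarios[label].ci_lo,
                    settings.printed_scenarios[label].ci_hi,
                ),
            )
            for label in ("best_case", "worst_case")
        ]
    else:
        sv = pooled["saved_time_concurrent"]
        concurrent = SavedTimeRow(
            label="concurrent_reader",
            saved_time_s=sv.mean,
            saved_time_ci=(sv.ci_lo, sv.ci_hi),
        )
        best, worst = derive_scenarios(pooled["no_cad"], settings.scenario)
        scen_rows = [
            SavedTimeRow(
                label=f"prescreen_{s.label.value}",
                saved_time_s=s.saved_time_s,
                saved_time_ci=s.saved_time_ci,
            )
            for s in (best, worst)
        ]
    return [concurrent, *scen_rows]


def _scenario_frame(settings: Settings, pooled_no_cad: PooledEstimate) -> pd.DataFrame:
    best, worst = derive_scenarios(pooled_no_cad, settings.scenario)
    return pd.DataFrame.from_records(
        [
            {
                "label": s.label.value,
                "workload_reduction": s.workload_reduction,
                "saved_time_s": s.saved_time_s,
                "ci_lo_s": s.saved_time_ci[0],
                "ci_hi_s": s.saved_time_ci[1],
            }
            for s in (best, worst)
        ]
    )


def _check_consistency(
    results: Sequence[BreakEvenResult], settings: Settings, rows: Sequence[SavedTimeRow]
) -> None:
    by_row = {r.label: r for r in rows}
    salaries = {c.name: float(c.hourly_cost_eur_printed) for c in settings.countries}
    for res in results:
        if res.min_workload_scans is None:
            continue
        price = settings.pricing_model(res.pricing_kind.value).price_eur
        dt = by_row[res.reading_mode_or_scenario].saved_time_s
        w = res.min_workload_scans[0]
        c = per_case_cost(salaries[res.country], dt)
        if abs(w * c - price) > 1e-9 * price:
            raise ConsistencyError(
                f"W*C != P for {res.reading_mode_or_scenario}/{res.pricing_kind.value}/"
                f"{res.country}: {w * c} vs {price}"
            )
    # lower salary => more scans needed, at every workload cell
    ordered = sorted(salaries, key=salaries.get)  # ascending salary
    for row in rows:
        if row.saved_time_s <= 0:
            continue
        for kind in (PricingKind.ONE_OFF_LICENSE, PricingKind.YEARLY_SUBSCRIPTION):
            ws = [
                r.min_workload_scans[0]
                for name in ordered
                for r in results
                if r.country == name
                and r.pricing_kind == kind
                and r.reading_mode_or_scenario == row.label
            ]
            if any(b >= a for a, b in zip(ws, ws[1:])):
                raise ConsistencyError(
                    f"workload not decreasing in salary for {row.label}/{kind.value}"
                )


def run_breakeven(config: RunConfig | None = None) -> ReportBundle:
    """Full pipeline: pool, derive scenarios, evaluate the grid, render reports.

    Internal consistency (W*C=P, salary ordering, curve monotonicity) is
    verified before anything is written; a failure raises
    :class:`ConsistencyError` and produces no partial output files.
    """
    config = config or RunConfig()
    settings = load_settings(config.settings)
    pooled, pooled_df = run_pool(config.model_copy(update={"output_dir": None}))
    rows = _saved_time_rows(config, settings, pooled)
    if config.include_second_reader:
        lo_inc, hi_inc = summarize_second_reader(load_corpus(config.corpus))
        rows_with_sr = [
            *rows,
            SavedTimeRow(label="second_reader", saved_time_s=-hi_inc),
        ]
    else:
        lo_inc = hi_inc = float("nan")
        rows_with_sr = rows

    results = evaluate_grid(
        settings.countries,
        settings.pricing,
        rows_with_sr,
        use_printed_salaries=config.use_printed_salaries,
    )
    core = [r for r in results if r.reading_mode_or_scenario != "second_reader"]
    table2 = render_table2(core)
    discrepancies = compare_to_snapshot(table2) if config.replication else []

    lo, hi, step = config.saved_time_grid
    grid = list(np.arange(lo, hi + step / 2, step))
    price_one_off = settings.pricing_model("one_off_license").price_eur
    curves = []
    for c in settings.countries:
        s = float(c.hourly_cost_eur_printed) if config.use_printed_salaries else c.hourly_cost_eur
        curves.append((c.name, breakeven_curve(price_one_off, s, grid)))

    _check_consistency(results, settings, rows_with_sr)

    scen_source = pooled["no_cad"]
    if config.replication:
        p = settings.printed_pooled["no_cad"]
        scen_source = PooledEstimate(
            mean=p.mean, ci_lo=p.ci_lo, ci_hi=p.ci_hi, k_studies=1,
            method=PoolingMethod.UNWEIGHTED,
        )
    bundle = ReportBundle(
        pooled=pooled,
        second_reader_range_s=(lo_inc, hi_inc),
        scenario_table=_scenario_frame(settings, scen_source),
        results=results,
        table2=table2,
        discrepancies=discrepancies,
        curves=pd.DataFrame(),
        metadata={
            "config": json.loads(config.model_dump_json()),
            "config_digest": config.digest(),
            "replication": config.replication,
        },
    )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pooled_df.to_csv(out / "pooled.csv", index=False)
        bundle.scenario_table.to_csv(out / "scenarios.csv", index=False)
        table2.to_csv(out / "table2.csv", index=False)
        pd.DataFrame(
            [d.__dict__ for d in discrepancies],
            columns=["scenario", "pricing", "country", "computed", "printed"],
        ).to_csv(out / "table2_discrepancies.csv", index=False)
        bundle.curves = render_fig1(
            curves, plot_path=out / "fig1.png", csv_path=out / "fig1.csv"
        )
        (out / "run_metadata.json").write_text(json.dumps(bundle.metadata, indent=1))
    else:
        bundle.curves = render_fig1(curves)
    return bundle
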