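"""Rendering of the pooled-evidence table, break-even table and workload curves.

Display conventions follow the published tables: EUR costs to one
decimal, workloads in thousands of scans to one decimal, saved times to
whole seconds, all rounded half-up, CI bounds joined with an en dash.
Every rendered cell keeps its unrounded source value alongside the
display string, and any cell that differs from the checked-in
transcription of the published break-even table is listed in a
first-class discrepancy report rather than silently forced.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .corpus import PricingKind
from .economics import BreakEvenResult

EN_DASH = "–"

#: Table layout: (row label, pricing kinds) in publication order.
ROW_ORDER = ["concurrent_reader", "prescreen_best_case", "prescreen_worst_case"]
PRICING_ORDER = [
    PricingKind.PAY_PER_USE,
    PricingKind.ONE_OFF_LICENSE,
    PricingKind.YEARLY_SUBSCRIPTION,
]
COUNTRY_ORDER = ["USA", "UK", "Poland"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.9625 -> 1.0 at one decimal), as tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_cell(point: float, ci_lo: float, ci_hi: float, ndigits: int = 1) -> str:
    """Render ``point (95% CI: lo-hi)`` at the table's display precision."""
    fmt = f"{{:.{ndigits}f}}"
    return (
        f"{fmt.format(round_half_up(point, ndigits))} "
        f"(95% CI: {fmt.format(round_half_up(ci_lo, ndigits))}"
        f"{EN_DASH}{fmt.format(round_half_up(ci_hi, ndigits))})"
    )


_CELL_RE = re.compile(
    r"^\s*(-?[\d.]+)\s*\(95% CI:\s*(-?[\d.]+)\s*[–—-]\s*(-?[\d.]+)\)\s*$"
)


def parse_cell(cell: str) -> tuple[float, float, float]:
    """Invert :func:`format_cell`: recover (point, ci_lo, ci_hi) at display precision."""
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"unparseable table cell: {cell!r}")
    return tuple(float(g) for g in m.groups())


def _result_numbers(res: BreakEvenResult) -> tuple[float, float, float]:
    """Cell numbers on the display scale: EUR for costs, thousands for workloads."""
    if res.per_case_cost_eur is not None:
        return res.per_case_cost_eur
    point, lo, hi = res.min_workload_scans
    return point / 1000.0, lo / 1000.0, hi / 1000.0


def render_table2(
    results: Sequence[BreakEvenResult],
    rows: Sequence[str] = ROW_ORDER,
    countries: Sequence[str] = COUNTRY_ORDER,
) -> pd.DataFrame:
    """Break-even table: one row per scenario x pricing model, one column per country.

    Cells are "point (95% CI: lo-hi)" strings; costs in EUR, workloads in
    thousands of CT scans.  Raises if any requested grid cell is absent.
    """
    if not results:
        raise ValueError("no break-even results to render")
    index = {
        (r.reading_mode_or_scenario, r.pricing_kind, r.country): r for r in results
    }
    records = []
    for row_label in rows:
        for pricing in PRICING_ORDER:
            rec = {"scenario": row_label, "pricing": pricing.value}
            for country in countries:
                key = (row_label, pricing, country)
                if key not in index:
                    raise ValueError(f"missing grid cell: {key}")
                res = index[key]
                if res.no_break_even:
                    rec[country] = "no break-even"
                else:
                    rec[country] = format_cell(*_result_numbers(res))
            records.append(rec)
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class Discrepancy:
    """A rendered cell that differs from the published table."""

    scenario: str
    pricing: str
    country: str
    computed: str
    printed: str

    def __str__(self) -> str:
        return (
            f"{self.scenario}/{self.pricing}/{self.country}: "
            f"computed {self.computed!r} vs printed {self.printed!r}"
        )


def load_table2_snapshot() -> pd.DataFrame:
    """Checked-in transcription of the published break-even table."""
    text = resources.files("cad_breakeven.data").joinpath("table2_printed.csv").read_text()
    return pd.read_csv(io.StringIO(text))


def compare_to_snapshot(
    rendered: pd.DataFrame, snapshot: Optional[pd.DataFrame] = None
) -> list[Discrepancy]:
    """Cell-by-cell comparison of a rendered table against the published one."""
    if snapshot is None:
        snapshot = load_table2_snapshot()
    snap = {
        (r["scenario"], r["pricing"]): r for _, r in snapshot.iterrows()
    }
    out = []
    for _, row in rendered.iterrows():
        key = (row["scenario"], row["pricing"])
        if key not in snap:
            continue
        for country in COUNTRY_ORDER:
            if country in row and row[country] != snap[key][country]:
                out.append(
                    Discrepancy(
                        scenario=row["scenario"],
                        pricing=row["pricing"],
                        country=country,
                        computed=row[country],
                        printed=snap[key][country],
                    )
                )
    return out


def pooled_table(pooled: dict[str, "PooledEstimate"]) -> pd.DataFrame:  # noqa: F821
    """Long-format pooling report: one row per arm."""
    records = [
        {
            "arm": arm,
            "mean_s": p.mean,
            "ci_lo_s": p.ci_lo,
            "ci_hi_s": p.ci_hi,
            "k_studies": p.k_studies,
            "tau2": p.tau2,
            "method": p.method.value,
            "display": format_cell(p.mean, p.ci_lo, p.ci_hi, ndigits=0),
        }
        for arm, p in pooled.items()
    ]
    return pd.DataFrame.from_records(records)


def render_fig1(
    curves: Sequence[tuple[str, Sequence[tuple[float, float]]]],
    plot_path: Optional[Path] = None,
    csv_path: Optional[Path] = None,
) -> pd.DataFrame:
    """Workload-for-break-even curves, one per country, over a saved-time grid.

    Each series must be strictly decreasing in saved time (W = P/(S dt));
    a non-monotone series indicates an internal inconsistency upstream.
    Returns the plotted points; optionally writes a CSV and a figure.
    """
    if not curves:
        raise ValueError("at least one country curve required")
    records = []
    for country, series in curves:
        workloads = [w for _, w in series]
        if any(b >= a for a, b in zip(workloads, workloads[1:])):
            raise ValueError(f"curve for {country} is not strictly decreasing in saved time")
        for dt, w in series:
            records.append({"country": country, "saved_time_s": dt, "min_workload_scans": w})
    df = pd.DataFrame.from_records(records)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for country, series in curves:
            xs = [dt for dt, _ in series]
            ys = [w / 1000.0 for _, w in series]
            ax.plot(xs, ys, label=country)
        ax.set_xlabel("Saved reading time per scan (s)")
        ax.set_ylabel("Minimum workload for break-even\n(thousand CT scans)")
        ax.legend(title="Salary setting")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df
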