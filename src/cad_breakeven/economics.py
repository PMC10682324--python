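"""Break-even prices and minimum workloads.

Monetising Delta-t seconds of saved radiologist time at an hourly cost
of S euros gives a per-case value C = S * Delta-t / 3600.  Under
pay-per-use pricing, C is the break-even per-case price.  For a fixed
price P (one-off license or annual subscription fee) the minimum
workload to recoup it is W = P / C scans (per period for subscriptions),
so W * C = P identically.

Confidence intervals propagate through these monotone transforms by
mapping the Delta-t interval endpoints: C is increasing in Delta-t and
W is decreasing, so the workload bounds swap.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, model_validator

from .corpus import CountrySetting, PricingKind, PricingModel

SECONDS_PER_HOUR = 3600.0


class WorkloadPeriod(str, Enum):
    TOTAL = "total"
    PER_YEAR = "per_year"


class SavedTimeRow(BaseModel):
    """One reading mode or scenario: saved time per scan with its 95% CI.

    Negative saved time (a second reader adds time) is allowed and marks
    the row as having no break-even.
    """

    label: str
    saved_time_s: float
    saved_time_ci: Optional[tuple[float, float]] = None


class BreakEvenResult(BaseModel):
    """One cell of the break-even grid.

    Pay-per-use pricing yields a per-case cost; license and subscription
    pricing yield a minimum workload (total scans, or scans per year).
    A mode that saves no time carries neither and is flagged
    ``no_break_even``.
    """

    country: str
    reading_mode_or_scenario: str
    pricing_kind: PricingKind
    per_case_cost_eur: Optional[tuple[float, float, float]] = None
    min_workload_scans: Optional[tuple[float, float, float]] = None
    workload_period: Optional[WorkloadPeriod] = None
    no_break_even: bool = False

    @model_validator(mode="after")
    def _check(self) -> "BreakEvenResult":
        if self.no_break_even:
            if self.per_case_cost_eur is not None or self.min_workload_scans is not None:
                raise ValueError("a no-break-even result carries no estimates")
            return self
        present = [x for x in (self.per_case_cost_eur, self.min_workload_scans) if x is not None]
        if len(present) != 1:
            raise ValueError("exactly one of per_case_cost_eur / min_workload_scans must be set")
        point, lo, hi = present[0]
        if not lo <= point <= hi:
            raise ValueError(f"CI ({lo}, {hi}) must bracket the point estimate {point}")
        return self


def per_case_cost(hourly_cost_eur: float, saved_time_s: float) -> float:
    """EUR value of the radiologist time saved on one scan: S * dt / 3600."""
    if hourly_cost_eur < 0 or saved_time_s < 0:
        raise ValueError("hourly cost and saved time must be non-negative")
    return hourly_cost_eur * saved_time_s / SECONDS_PER_HOUR


def min_workload(price_eur: float, hourly_cost_eur: float, saved_time_s: float) -> float:
    """Number of CAD-assisted readings needed to recoup a fixed price.

    W = P / (S * dt / 3600); W * C = P by construction.
    """
    if price_eur <= 0 or hourly_cost_eur <= 0:
        raise ValueError("price and hourly cost must be positive")
    if saved_time_s <= 0:
        raise ValueError("break-even unreachable: saved time per scan is not positive")
    return price_eur / per_case_cost(hourly_cost_eur, saved_time_s)


def propagate_ci(
    transform: str,
    hourly_cost_eur: float,
    saved_time_ci: tuple[float, float],
    price_eur: Optional[float] = None,
) -> tuple[float, float]:
    """Map a saved-time CI through the cost or workload transform.

    Cost is increasing in saved time, so bound order is preserved;
    workload is decreasing, so bounds swap.  Returned ascending.
    """
    lo, hi = saved_time_ci
    if lo > hi:
        raise ValueError(f"saved-time CI ({lo}, {hi}) must satisfy lo <= hi")
    if transform == "cost":
        return per_case_cost(hourly_cost_eur, lo), per_case_cost(hourly_cost_eur, hi)
    if transform == "workload":
        if price_eur is None:
            raise ValueError("workload propagation needs price_eur")
        if lo <= 0:
            raise ValueError("workload CI needs a strictly positive saved-time lower bound")
        return (
            min_workload(price_eur, hourly_cost_eur, hi),
            min_workload(price_eur, hourly_cost_eur, lo),
        )
    raise ValueError(f"unknown transform {transform!r}")


def _cell(
    country: CountrySetting,
    hourly_eur: float,
    pricing: PricingModel,
    row: SavedTimeRow,
) -> BreakEvenResult:
    base = dict(
        country=country.name,
        reading_mode_or_scenario=row.label,
        pricing_kind=pricing.kind,
    )
    if row.saved_time_s <= 0:
        return BreakEvenResult(**base, no_break_even=True)
    ci = row.saved_time_ci or (row.saved_time_s, row.saved_time_s)
    if pricing.kind == PricingKind.PAY_PER_USE:
        point = per_case_cost(hourly_eur, row.saved_time_s)
        lo, hi = propagate_ci("cost", hourly_eur, ci)
        return BreakEvenResult(**base, per_case_cost_eur=(point, lo, hi))
    point = min_workload(pricing.price_eur, hourly_eur, row.saved_time_s)
    lo, hi = propagate_ci("workload", hourly_eur, ci, price_eur=pricing.price_eur)
    period = (
        WorkloadPeriod.PER_YEAR
        if pricing.kind == PricingKind.YEARLY_SUBSCRIPTION
        else WorkloadPeriod.TOTAL
    )
    return BreakEvenResult(**base, min_workload_scans=(point, lo, hi), workload_period=period)


def evaluate_grid(
    countries: Sequence[CountrySetting],
    pricing_models: Sequence[PricingModel],
    rows: Sequence[SavedTimeRow],
    use_printed_salaries: bool = True,
) -> list[BreakEvenResult]:
    """Evaluate every country x pricing-model x reading-mode/scenario cell.

    With ``use_printed_salaries`` the whole-euro hourly costs (the
    precision at which salary figures are quoted) enter the arithmetic;
    otherwise the exact currency-converted values do.
    """
    if not countries or not pricing_models or not rows:
        raise ValueError("countries, pricing models and rows must all be non-empty")
    results = []
    for row in rows:
        for pricing in pricing_models:
            for country in countries:
                s = (
                    float(country.hourly_cost_eur_printed)
                    if use_printed_salaries
                    else country.hourly_cost_eur
                )
                results.append(_cell(country, s, pricing, row))
    return results


def breakeven_curve(
    price_eur: float,
    hourly_cost_eur: float,
    saved_time_grid: Sequence[float],
) -> list[tuple[float, float]]:
    """Minimum workload as a function of saved reading time, W(dt) = P/(S dt/3600)."""
    for dt in saved_time_grid:
        if dt <= 0:
            raise ValueError(f"saved-time grid values must be positive, got {dt}")
    return [
        (float(dt), min_workload(price_eur, hourly_cost_eur, dt)) for dt in saved_time_grid
    ]
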