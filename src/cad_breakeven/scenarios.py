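"""Pre-screening reader scenarios.

When CAD triages scans before any radiologist sees them, every scan it
rules out saves a full unaided reading.  With nodule prevalence p and a
fraction r of nodule-free scans ruled out, the expected workload (and
hence reading-time) reduction is r * (1 - p).  The prevalence range maps
to a best case (low prevalence, more scans ruled out) and a worst case.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, model_validator

from .corpus import ScenarioConfig
from .pooling import PooledEstimate

__all__ = [
    "ScenarioConfig",
    "ScenarioLabel",
    "PrescreenScenario",
    "workload_reduction",
    "scenario_saved_time",
    "derive_scenarios",
]


class ScenarioLabel(str, Enum):
    BEST_CASE = "best_case"
    WORST_CASE = "worst_case"


class PrescreenScenario(BaseModel):
    """A workload-reduction fraction and the implied saved time with CI."""

    label: ScenarioLabel
    workload_reduction: float
    saved_time_s: float
    saved_time_ci: tuple[float, float]

    @model_validator(mode="after")
    def _check(self) -> "PrescreenScenario":
        if not 0 <= self.workload_reduction <= 1:
            raise ValueError("workload_reduction must be in [0, 1]")
        lo, hi = self.saved_time_ci
        if not lo <= self.saved_time_s <= hi:
            raise ValueError(f"CI ({lo}, {hi}) must bracket saved time {self.saved_time_s}")
        return self


def workload_reduction(prevalence: float, ruleout_fraction: float) -> float:
    """Fraction of scans a pre-screening CAD removes from the reading list.

    Nodule-positive scans are never ruled out; a fraction
    ``ruleout_fraction`` of the nodule-free scans is.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    if not 0 <= ruleout_fraction <= 1:
        raise ValueError(f"ruleout_fraction must be in [0, 1], got {ruleout_fraction}")
    return ruleout_fraction * (1.0 - prevalence)


def scenario_saved_time(
    no_cad_pooled: PooledEstimate,
    reduction: float,
    label: ScenarioLabel | str = ScenarioLabel.BEST_CASE,
) -> PrescreenScenario:
    """Mean reading time saved per scan when a fraction of scans is skipped.

    The reduction fraction is applied to the pooled no-CAD time and to
    both CI bounds; no additional uncertainty on prevalence or the
    rule-out fraction is propagated (that variation is carried by the
    best/worst scenario pair).
    """
    if not 0 <= reduction <= 1:
        raise ValueError(f"reduction must be in [0, 1], got {reduction}")
    return PrescreenScenario(
        label=ScenarioLabel(label),
        workload_reduction=reduction,
        saved_time_s=reduction * no_cad_pooled.mean,
        saved_time_ci=(reduction * no_cad_pooled.ci_lo, reduction * no_cad_pooled.ci_hi),
    )


def derive_scenarios(
    no_cad_pooled: PooledEstimate,
    config: ScenarioConfig,
    quote_to_percent: bool = True,
) -> tuple[PrescreenScenario, PrescreenScenario]:
    """(best_case, worst_case) scenarios from a prevalence range.

    Best case: prevalence at the low end of the range, so the largest
    share of scans is nodule-free and ruled out.  Scenario fractions are
    quoted to the whole percent (0.624 -> 62%) and applied as quoted,
    which is how such workload-reduction figures are stated; pass
    ``quote_to_percent=False`` to apply the exact fractions.
    """

    def _quote(x: float) -> float:
        if not quote_to_percent:
            return x
        from .report import round_half_up

        return round_half_up(x, 2)

    best = scenario_saved_time(
        no_cad_pooled,
        _quote(workload_reduction(config.prevalence_lo, config.ruleout_fraction)),
        ScenarioLabel.BEST_CASE,
    )
    worst = scenario_saved_time(
        no_cad_pooled,
        _quote(workload_reduction(config.prevalence_hi, config.ruleout_fraction)),
        ScenarioLabel.WORST_CASE,
    )
    return best, worst
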