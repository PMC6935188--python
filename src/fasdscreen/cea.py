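"""Incremental cost-effectiveness ratios between two strategy arms.

The ICER divides the difference in discounted cost by the difference in
discounted years lived with an FASD diagnosis, both per 100 individuals
screened.  Screening typically saves money while forgoing diagnosed years
(the south-west quadrant of the cost-effectiveness plane); such ICERs are
positive and read as dollars saved per diagnosed year forgone, to be judged
against a willingness-to-accept threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import StrategyResult
from .parameters import ValidationError

__all__ = ["IcerResult", "compare", "classify_quadrant"]


@dataclass
class IcerResult:
    """Incremental cost, effectiveness and their ratio, per 100 screened."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    quadrant: str  # NE | NW | SE | SW | on-axis
    dominance: str | None = None  # "comparator" | "reference" | None

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "quadrant": self.quadrant,
            "dominance": self.dominance,
        }


def classify_quadrant(delta_cost: float, delta_effect: float) -> str:
    """Quadrant of the cost-effectiveness plane (effect on x, cost on y)."""
    if delta_cost == 0.0 or delta_effect == 0.0:
        return "on-axis"
    if delta_effect > 0:
        return "NE" if delta_cost > 0 else "SE"
    return "NW" if delta_cost > 0 else "SW"


def compare(
    reference: StrategyResult,
    comparator: StrategyResult,
    cohort_size: float = 100.0,
) -> IcerResult:
    """ICER of ``comparator`` (screening) against ``reference`` (no screening).

    Deltas are comparator minus reference, normalized to 100 individuals
    screened.  The ICER is undefined when the incremental effectiveness is
    zero (equal effect: dominance or equality is flagged instead of a
    division).  A dominance flag marks draws where one arm is at least as
    good on both axes.
    """
    if reference.strategy.model_start_age != comparator.strategy.model_start_age:
        raise ValidationError(
            "compared strategies must come from the same comparison model "
            "(equal start ages)"
        )
    ref_cost, ref_eff = reference.per_100(cohort_size)
    cmp_cost, cmp_eff = comparator.per_100(cohort_size)
    delta_cost = cmp_cost - ref_cost
    delta_effect = cmp_eff - ref_eff
    quadrant = classify_quadrant(delta_cost, delta_effect)
    dominance = None
    if delta_cost <= 0 and delta_effect >= 0 and (delta_cost < 0 or delta_effect > 0):
        dominance = "comparator"
    elif delta_cost >= 0 and delta_effect <= 0 and (delta_cost > 0 or delta_effect < 0):
        dominance = "reference"
    icer = None if delta_effect == 0.0 else delta_cost / delta_effect
    return IcerResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        quadrant=quadrant,
        dominance=dominance,
    )
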