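"""Decision tree and Markov cohort engine.

A hypothetical cohort of children suspected of FASD is split by the decision
tree (screen result, or direct referral under no screening) into initial
states and then advanced in one-year cycles until age 18:

* ``PENDING_FASD`` -- FASD, diagnostic testing scheduled but not yet done
  (true positives awaiting the lag, or the whole FASD group under no
  screening);
* ``UNDIAGNOSED`` -- FASD, missed by screening (false negatives), converting
  to ``DIAGNOSED`` at the future-diagnosis rate once the testing age has
  been reached, with repeat screening and diagnostic testing charged at
  conversion;
* ``DIAGNOSED`` -- FASD with an accurate diagnosis (the effectiveness
  outcome accrues here, one diagnosed year per person per cycle);
* ``PENDING_NO_FASD`` -- no FASD, scheduled for (rule-out) diagnostic
  testing: false positives under screening, the whole non-FASD group under
  no screening;
* ``NO_FASD`` -- no FASD, ruled out or never tested;
* ``DEAD`` -- absorbing; background life-table mortality scaled by
  state-specific standardized mortality ratios.

Costs and diagnosed years are accrued per cycle with a half-cycle
correction (mid-cycle discount evaluation by default) and discounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ModelParameters, MortalityParams, ToolProfile, ValidationError

__all__ = [
    "STATES",
    "LIVING_STATES",
    "LifeTable",
    "StrategyDefinition",
    "CycleRecord",
    "StrategyResult",
    "initial_distribution",
    "state_mortality",
    "discount_factor",
    "advance_cycle",
    "run_strategy",
    "comparison_strategies",
    "run_comparison_pair",
]

STATES = (
    "PENDING_FASD",
    "UNDIAGNOSED",
    "DIAGNOSED",
    "PENDING_NO_FASD",
    "NO_FASD",
    "DEAD",
)
LIVING_STATES = STATES[:-1]

_CONSERVATION_TOL = 1e-7


@dataclass
class LifeTable:
    """Annual background death probabilities ``q(a)`` indexed by age."""

    qx: np.ndarray

    def __post_init__(self) -> None:
        self.qx = np.asarray(self.qx, dtype=float)
        if self.qx.ndim != 1 or len(self.qx) == 0:
            raise ValidationError("life table must be a non-empty 1-d array")
        if np.any((self.qx < 0) | (self.qx >= 1)):
            raise ValidationError("life-table probabilities must lie in [0, 1)")

    @property
    def end_age(self) -> int:
        return len(self.qx)

    def q(self, age: int) -> float:
        if not 0 <= age < len(self.qx):
            raise ValidationError(
                f"life table covers ages [0, {len(self.qx)}), requested {age}"
            )
        return float(self.qx[age])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise ValidationError(f"life table {path}: needs columns 'age' and 'qx'")
        df = df.sort_values("age")
        ages = df["age"].to_numpy()
        if not np.array_equal(ages, np.arange(len(ages))):
            raise ValidationError(
                f"life table {path}: ages must be consecutive integers from 0"
            )
        return cls(df["qx"].to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": np.arange(len(self.qx)), "qx": self.qx}).to_csv(
            path, index=False
        )


@dataclass
class StrategyDefinition:
    """One arm of a comparison.

    Both arms of a comparison share ``model_start_age`` and ``testing_age``;
    only whether a screen filters entry to diagnostic testing differs.
    """

    kind: str  # "screen" | "no_screen"
    tool: ToolProfile | None
    model_start_age: int
    testing_age: int

    def __post_init__(self) -> None:
        if self.kind not in ("screen", "no_screen"):
            raise ValidationError(f"strategy kind must be screen/no_screen, got {self.kind!r}")
        if self.kind == "screen" and self.tool is None:
            raise ValidationError("screen strategy requires a tool profile")
        if self.testing_age < self.model_start_age:
            raise ValidationError("testing age cannot precede the model start age")


@dataclass
class CycleRecord:
    """Audit trace for one cycle: occupancy after transitions plus accruals."""

    cycle: int
    age: int
    occupancy: dict[str, float]
    cost: float
    discounted_cost: float
    diagnosed_years: float
    discounted_diagnosed_years: float


@dataclass
class StrategyResult:
    """Discounted totals per cohort, with the full cycle trace."""

    strategy: StrategyDefinition
    total_cost: float
    total_diagnosed_years: float
    trace: list[CycleRecord] = field(default_factory=list)

    def per_100(self, cohort_size: float) -> tuple[float, float]:
        scale = 100.0 / cohort_size
        return self.total_cost * scale, self.total_diagnosed_years * scale

    def trace_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.trace:
            row = {"cycle": rec.cycle, "age": rec.age}
            row.update(rec.occupancy)
            row.update(
                cost=rec.cost,
                discounted_cost=rec.discounted_cost,
                diagnosed_years=rec.diagnosed_years,
                discounted_diagnosed_years=rec.discounted_diagnosed_years,
            )
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------


def initial_distribution(
    params: ModelParameters, strategy: StrategyDefinition
) -> dict[str, float]:
    """Split the cohort into initial states via the decision tree.

    Under screening, true positives await diagnostic testing
    (``PENDING_FASD``), false negatives sit in ``UNDIAGNOSED``, false
    positives await rule-out testing (``PENDING_NO_FASD``) and true
    negatives are never tested.  Under no screening everyone proceeds to
    diagnostic testing at the testing age.
    """
    n = params.cohort_size
    fasd = n * params.prevalence
    no_fasd = n - fasd
    sv = {state: 0.0 for state in STATES}
    if strategy.kind == "screen":
        tool = strategy.tool
        assert tool is not None
        sv["PENDING_FASD"] = fasd * tool.sensitivity
        sv["UNDIAGNOSED"] = fasd * (1.0 - tool.sensitivity)
        sv["PENDING_NO_FASD"] = no_fasd * (1.0 - tool.specificity)
        sv["NO_FASD"] = no_fasd * tool.specificity
    else:
        sv["PENDING_FASD"] = fasd
        sv["PENDING_NO_FASD"] = no_fasd
    _assert_conserved(sv, n)
    return sv


def _assert_conserved(sv: Mapping[str, float], n: float) -> None:
    total = sum(sv.values())
    if abs(total - n) > _CONSERVATION_TOL * max(1.0, n) or min(sv.values()) < -1e-12:
        raise RuntimeError(
            f"state occupancies violate conservation: total {total!r} vs cohort {n!r}"
        )


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------


def state_mortality(q_background: float, state: str, m: MortalityParams) -> float:
    """Annual death probability in a state: background ``q`` times the SMR.

    FASD states carry the diagnosed-FASD SMR, elevated by the undiagnosed
    multiplier for missed cases; non-FASD states carry the no-FASD SMR.
    Products are capped at 1.
    """
    if not 0.0 <= q_background < 1.0:
        raise ValidationError("background death probability must lie in [0, 1)")
    if state in ("DIAGNOSED", "PENDING_FASD"):
        ratio = m.smr_diagnosed
    elif state == "UNDIAGNOSED":
        ratio = m.smr_diagnosed * m.undiagnosed_multiplier
    elif state in ("NO_FASD", "PENDING_NO_FASD"):
        ratio = m.smr_no_fasd
    elif state == "DEAD":
        return 0.0
    else:
        raise ValidationError(f"unknown state {state!r}")
    return min(1.0, q_background * ratio)


def discount_factor(cycle: int, r: float, half_cycle: str = "mid_cycle") -> float:
    """Discount weight for accruals in a cycle.

    ``mid_cycle`` evaluates the factor at ``(1 + r) ** -(cycle + 0.5)``,
    implementing the half-cycle correction as a mid-cycle transition;
    ``trapezoidal`` averages the start- and end-of-cycle factors.
    """
    if r < 0:
        raise ValidationError("discount rate must be >= 0")
    if half_cycle == "mid_cycle":
        return float((1.0 + r) ** -(cycle + 0.5))
    if half_cycle == "trapezoidal":
        return float(((1.0 + r) ** -cycle + (1.0 + r) ** -(cycle + 1)) / 2.0)
    raise ValidationError(f"unknown half-cycle variant {half_cycle!r}")


def _annual_state_costs(params: ModelParameters) -> dict[str, float]:
    c = params.effective_costs()
    pending_fasd = {
        "undiagnosed": c.undiagnosed_annual,
        "no_fasd": c.no_fasd_annual,
        "diagnosed": c.diagnosed_annual,
    }[params.pending_fasd_cost]
    return {
        "PENDING_FASD": pending_fasd,
        "UNDIAGNOSED": c.undiagnosed_annual,
        "DIAGNOSED": c.diagnosed_annual,
        "PENDING_NO_FASD": c.no_fasd_annual,
        "NO_FASD": c.no_fasd_annual,
        "DEAD": 0.0,
    }


def advance_cycle(
    sv: Mapping[str, float],
    cycle: int,
    params: ModelParameters,
    strategy: StrategyDefinition,
    life_table: LifeTable,
) -> tuple[dict[str, float], float, float]:
    """Advance the cohort one cycle.

    Order of events: (a) deaths; (b) diagnostic testing in the cycle
    containing the testing age (one-off testing cost per person tested,
    imperfect test sensitivity routes missed FASD cases to
    ``UNDIAGNOSED``); (c) future-diagnosis conversions of missed cases, from
    the testing cycle onward, paying repeat screening plus testing; (d)
    annual state costs (the first year of life is charged at the newborn
    rate for every living person when the model starts at birth); (e)
    diagnosed-year accrual; (f) screening charged once, in cycle 0 of a
    screening arm.  Returns the new state vector plus the *undiscounted*
    cost and diagnosed years accrued; the caller applies the half-cycle
    discount weight.
    """
    n = params.cohort_size
    _assert_conserved(sv, n)
    age = strategy.model_start_age + cycle
    sv = dict(sv)
    costs = params.effective_costs()
    cost = 0.0

    # (f) screening: every cohort member is screened when the arm starts.
    if strategy.kind == "screen" and cycle == 0:
        assert strategy.tool is not None
        cost += n * strategy.tool.unit_cost

    # (a) deaths
    q_bg = life_table.q(age)
    for state in LIVING_STATES:
        dying = sv[state] * state_mortality(q_bg, state, params.mortality)
        sv[state] -= dying
        sv["DEAD"] += dying

    # (b) scheduled diagnostic testing
    if age == strategy.testing_age:
        tested = sv["PENDING_FASD"] + sv["PENDING_NO_FASD"]
        cost += tested * costs.diagnostic_testing
        confirmed = sv["PENDING_FASD"] * params.diagnostic_test_sensitivity
        sv["DIAGNOSED"] += confirmed
        sv["UNDIAGNOSED"] += sv["PENDING_FASD"] - confirmed
        sv["PENDING_FASD"] = 0.0
        sv["NO_FASD"] += sv["PENDING_NO_FASD"]
        sv["PENDING_NO_FASD"] = 0.0

    # (c) future diagnosis of missed cases (from the testing cycle onward)
    if age >= strategy.testing_age and sv["UNDIAGNOSED"] > 0:
        attempting = sv["UNDIAGNOSED"] * params.future_diagnosis_rate
        repeat_screen = strategy.tool.unit_cost if strategy.kind == "screen" else 0.0
        cost += attempting * (repeat_screen + costs.diagnostic_testing)
        converting = attempting * params.diagnostic_test_sensitivity
        sv["UNDIAGNOSED"] -= converting
        sv["DIAGNOSED"] += converting

    # (d) annual costs
    alive = sum(sv[s] for s in LIVING_STATES)
    if cycle == 0 and strategy.model_start_age == 0:
        cost += alive * costs.first_year
    else:
        annual = _annual_state_costs(params)
        cost += sum(sv[s] * annual[s] for s in LIVING_STATES)

    # (e) effectiveness
    diagnosed_years = sv["DIAGNOSED"]

    _assert_conserved(sv, n)
    return sv, cost, diagnosed_years


def run_strategy(
    params: ModelParameters,
    strategy: StrategyDefinition,
    life_table: LifeTable | None = None,
    record_trace: bool = True,
) -> StrategyResult:
    """Run one strategy arm over the full horizon.

    The horizon is ``end_age - model_start_age`` one-year cycles; survivors
    at the end age contribute nothing further.  Totals are discounted sums
    of the per-cycle accruals.
    """
    if life_table is None:
        from .synthetic import make_life_table

        life_table = make_life_table(end_age=params.end_age)
    horizon = params.end_age - strategy.model_start_age
    if horizon <= 0:
        raise ValidationError("model horizon must be positive")
    if life_table.end_age < params.end_age:
        raise ValidationError(
            f"life table covers ages up to {life_table.end_age}, "
            f"model needs {params.end_age}"
        )
    sv = initial_distribution(params, strategy)
    total_cost = 0.0
    total_effect = 0.0
    trace: list[CycleRecord] = []
    for cycle in range(horizon):
        sv, cost, effect = advance_cycle(sv, cycle, params, strategy, life_table)
        d = discount_factor(cycle, params.discount_rate, params.half_cycle)
        total_cost += d * cost
        total_effect += d * effect
        if record_trace:
            trace.append(
                CycleRecord(
                    cycle=cycle,
                    age=strategy.model_start_age + cycle,
                    occupancy=dict(sv),
                    cost=cost,
                    discounted_cost=d * cost,
                    diagnosed_years=effect,
                    discounted_diagnosed_years=d * effect,
                )
            )
    return StrategyResult(
        strategy=strategy,
        total_cost=total_cost,
        total_diagnosed_years=total_effect,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------


def comparison_strategies(
    params: ModelParameters,
) -> tuple[StrategyDefinition, StrategyDefinition]:
    """The (no-screen, screen) arm pair implied by the parameter set's tool.

    Both arms share the model start age (the tool's screening age) and the
    diagnostic-testing age (screening age plus lag): under no screening,
    children referred for suspected FASD are tested at the same age at which
    a positive screen would have led to testing.
    """
    tool = params.tool
    start = tool.screen_age
    testing = tool.testing_age
    no_screen = StrategyDefinition(
        kind="no_screen", tool=None, model_start_age=start, testing_age=testing
    )
    screen = StrategyDefinition(
        kind="screen", tool=tool, model_start_age=start, testing_age=testing
    )
    return no_screen, screen


def run_comparison_pair(
    params: ModelParameters,
    life_table: LifeTable | None = None,
    record_trace: bool = True,
) -> tuple[StrategyResult, StrategyResult]:
    """Run both arms of the comparison; returns (no-screen, screen) results."""
    if life_table is None:
        from .synthetic import make_life_table

        life_table = make_life_table(end_age=params.end_age)
    no_screen, screen = comparison_strategies(params)
    return (
        run_strategy(params, no_screen, life_table, record_trace),
        run_strategy(params, screen, life_table, record_trace),
    )
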