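"""Synthetic inputs: life tables, accuracy-study sets, and a
per-individual microsimulation that serves as an independent oracle for the
expected-value cohort engine.

The default life table is a stylized pediatric schedule -- an elevated
infant death probability followed by a low flat child rate -- with
magnitudes small enough that model results are insensitive to it, matching
the finding that mortality has minimal influence on cost-effectiveness
here.  A user-supplied CSV life table (columns ``age``, ``qx``) can stand
in for it everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import LifeTable, StrategyDefinition, StrategyResult, state_mortality
from .parameters import ModelParameters, ValidationError
from .pooling import AccuracyStudy, beta_sd, cap_extreme

__all__ = [
    "LifeTableSpec",
    "make_life_table",
    "zero_mortality_table",
    "make_accuracy_studies",
    "MicrosimResult",
    "microsimulate",
]


@dataclass
class LifeTableSpec:
    """Shape of the synthetic life table.

    Defaults (infant q0 = 0.005, flat child rate = 0.0002/year) are plausible
    Canadian pediatric magnitudes.
    """

    infant_q0: float = 0.005
    child_q_flat: float = 0.0002
    end_age: int = 18

    def __post_init__(self) -> None:
        for name in ("infant_q0", "child_q_flat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.05:
                raise ValidationError(f"{name} must lie in [0, 0.05], got {v!r}")
        if self.infant_q0 < self.child_q_flat:
            raise ValidationError("infant mortality must not fall below the child rate")
        if self.end_age < 1:
            raise ValidationError("end_age must be >= 1")


def make_life_table(spec: LifeTableSpec | None = None, end_age: int | None = None) -> LifeTable:
    """Build the synthetic life table: q(0) elevated, flat thereafter."""
    if spec is None:
        spec = LifeTableSpec(end_age=end_age if end_age is not None else 18)
    elif end_age is not None and end_age != spec.end_age:
        raise ValidationError("pass end_age either via spec or argument, not both")
    qx = np.full(spec.end_age, spec.child_q_flat, dtype=float)
    qx[0] = spec.infant_q0
    return LifeTable(qx)


def zero_mortality_table(end_age: int = 18) -> LifeTable:
    """An immortal cohort, for closed-form checks and published-table runs."""
    return LifeTable(np.zeros(end_age))


def make_accuracy_studies(
    true_p: float,
    k: int,
    n_range: tuple[int, int] = (30, 200),
    seed: int = 0,
) -> list[AccuracyStudy]:
    """Simulate ``k`` accuracy studies around a true proportion.

    Each study draws its group size uniformly from ``n_range`` and its
    successes binomially at ``true_p``; the study SD is imputed with the
    beta-distribution variance formula (extremes capped), mirroring how the
    real study tables are prepared for pooling.
    """
    if not 0.0 < true_p < 1.0:
        raise ValidationError("true_p must lie in (0, 1)")
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(k):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        p = rng.binomial(n, true_p) / n
        studies.append(
            AccuracyStudy(
                label=f"synthetic-{i}",
                proportion=p,
                group_n=n,
                sd=beta_sd(cap_extreme(p), n),
            )
        )
    return studies


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------

# Integer state codes for the vectorized simulation.
_PF, _UD, _DG, _PN, _NF, _DEAD = range(6)
_CODE_NAME = ("PENDING_FASD", "UNDIAGNOSED", "DIAGNOSED", "PENDING_NO_FASD", "NO_FASD", "DEAD")


@dataclass
class MicrosimResult:
    """Microsimulation totals (scaled to the cohort size) with Monte-Carlo SEs."""

    total_cost: float
    total_diagnosed_years: float
    se_cost: float
    se_diagnosed_years: float
    n_individuals: int


def microsimulate(
    params: ModelParameters,
    strategy: StrategyDefinition,
    life_table: LifeTable | None = None,
    n_individuals: int = 200_000,
    seed: int = 0,
) -> MicrosimResult:
    """Simulate individuals through the same per-person rules as the cohort engine.

    Every transition the cohort engine applies in expectation is drawn as an
    individual Bernoulli event here: screen outcome, diagnostic testing at
    the testing age, yearly death with SMR-scaled probability, and yearly
    future-diagnosis conversion for missed cases.  Costs and diagnosed years
    are accrued per individual with the same half-cycle discounting, then
    scaled to the cohort size.  Totals agree with the cohort engine within
    Monte-Carlo error; the standard errors returned are those of the scaled
    totals.
    """
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    if life_table is None:
        life_table = make_life_table(end_age=params.end_age)
    from .cohort import discount_factor  # local to avoid cycle at import time

    rng = np.random.default_rng(seed)
    n = n_individuals
    costs = params.effective_costs()
    horizon = params.end_age - strategy.model_start_age
    if horizon <= 0:
        raise ValidationError("model horizon must be positive")

    fasd = rng.random(n) < params.prevalence
    state = np.empty(n, dtype=np.int8)
    if strategy.kind == "screen":
        tool = strategy.tool
        assert tool is not None
        pos = np.where(
            fasd,
            rng.random(n) < tool.sensitivity,
            rng.random(n) < (1.0 - tool.specificity),
        )
        state[fasd & pos] = _PF
        state[fasd & ~pos] = _UD
        state[~fasd & pos] = _PN
        state[~fasd & ~pos] = _NF
    else:
        state[fasd] = _PF
        state[~fasd] = _PN

    annual_by_code = np.zeros(6)
    from .cohort import _annual_state_costs

    annual_named = _annual_state_costs(params)
    for code, name in enumerate(_CODE_NAME):
        annual_by_code[code] = annual_named[name]

    m = params.mortality
    q_by_code = np.zeros(6)
    cost = np.zeros(n)
    effect = np.zeros(n)
    repeat_screen = strategy.tool.unit_cost if strategy.kind == "screen" else 0.0

    for cycle in range(horizon):
        age = strategy.model_start_age + cycle
        d = discount_factor(cycle, params.discount_rate, params.half_cycle)
        cc = np.zeros(n)
        if cycle == 0 and strategy.kind == "screen":
            cc += strategy.tool.unit_cost
        # deaths
        q_bg = life_table.q(age)
        for code, name in enumerate(_CODE_NAME):
            q_by_code[code] = state_mortality(q_bg, name, m)
        dies = rng.random(n) < q_by_code[state]
        state[dies] = _DEAD
        # scheduled diagnostic testing
        if age == strategy.testing_age:
            pf = state == _PF
            pn = state == _PN
            cc[pf | pn] += costs.diagnostic_testing
            confirmed = pf & (rng.random(n) < params.diagnostic_test_sensitivity)
            state[confirmed] = _DG
            state[pf & ~confirmed] = _UD
            state[pn] = _NF
        # future diagnosis of missed cases
        if age >= strategy.testing_age:
            attempting = (state == _UD) & (
                rng.random(n) < params.future_diagnosis_rate
            )
            cc[attempting] += repeat_screen + costs.diagnostic_testing
            converted = attempting & (
                rng.random(n) < params.diagnostic_test_sensitivity
            )
            state[converted] = _DG
        # annual costs and effectiveness
        alive = state != _DEAD
        if cycle == 0 and strategy.model_start_age == 0:
            cc[alive] += costs.first_year
        else:
            cc[alive] += annual_by_code[state[alive]]
        cost += d * cc
        effect += d * (state == _DG)

    scale = params.cohort_size
    return MicrosimResult(
        total_cost=scale * float(cost.mean()),
        total_diagnosed_years=scale * float(effect.mean()),
        se_cost=scale * float(cost.std(ddof=1)) / np.sqrt(n) if n > 1 else np.inf,
        se_diagnosed_years=(
            scale * float(effect.std(ddof=1)) / np.sqrt(n) if n > 1 else np.inf
        ),
        n_individuals=n,
    )
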