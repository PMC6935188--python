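"""One-way (tornado) and probabilistic sensitivity analysis.

The probabilistic analysis redraws every uncertain parameter from its
published distributional assumption -- beta for proportions (moment
matched), bounded normal for screening and diagnostic-testing costs,
log-normal for the annual health-service costs (sampled on the
pre-inflation scale and then inflated), uniform for the future-diagnosis
rate (3-7%) and the undiagnosed mortality multiplier (1.0-1.2), and normal
truncated below 1 for the standardized mortality ratios -- reruns both arms,
and records the incremental cost and effectiveness of each draw.

Acceptability is framed against willingness-to-accept (WTA): screening
saves money but forgoes diagnosed years, so a draw in the south-west
quadrant is cost-effective at threshold ``lambda`` when its savings per
diagnosed year forgone, ``delta_cost / delta_effect``, is at least
``lambda``.  The resulting acceptability curve *decreases* in the
threshold -- the mirror image of a textbook willingness-to-pay CEAC -- which
is the direction the published curves show.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import IcerResult, classify_quadrant, compare
from .cohort import LifeTable, run_comparison_pair
from .parameters import ModelParameters, ValidationError
from .undiagnosed import ServiceRecommendation, undiagnosed_annual_cost

__all__ = [
    "DistributionSpec",
    "PsaDraw",
    "PsaResult",
    "CeacPoint",
    "TornadoEntry",
    "sample_parameter",
    "default_distributions",
    "run_psa",
    "ceac",
    "cep_quadrant_counts",
    "one_way",
    "discount_scenarios",
    "ONE_WAY_PARAMETERS",
]

logger = logging.getLogger(__name__)

_FAMILIES = (
    "beta",
    "normal_bounded",
    "log_normal",
    "uniform",
    "truncated_normal",
    "fixed",
)


@dataclass
class DistributionSpec:
    """Distributional assumption for one parameter."""

    family: str
    mean: float
    sd: float | None = None
    lower: float | None = None
    upper: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(
                f"{self.name or 'parameter'}: unknown distribution family "
                f"{self.family!r}"
            )
        if self.family == "beta":
            m, s = self.mean, self.sd
            if s is None or not 0.0 < m < 1.0:
                raise ValidationError(f"{self.name}: beta needs mean in (0,1) and an sd")
            if s * s >= m * (1.0 - m):
                raise ValidationError(
                    f"{self.name}: beta infeasible, sd^2 = {s * s:.5f} must be "
                    f"below mean*(1-mean) = {m * (1 - m):.5f}"
                )
        if self.family in ("uniform",) and (
            self.lower is None or self.upper is None or not self.lower < self.upper
        ):
            raise ValidationError(f"{self.name}: uniform needs lower < upper")


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a distributional assumption.

    Beta is parameterized by moment matching (``nu = m(1-m)/s^2 - 1``,
    ``alpha = m nu``, ``beta = (1-m) nu``); the bounded normal resamples
    until the draw lies within its bounds (default plus/minus 25% of the
    mean) rather than clipping, so no probability mass piles up at the
    bounds; the log-normal is moment matched to the stated mean and SD; the
    truncated normal resamples until it clears its lower bound.
    """
    m = spec.mean
    if spec.family == "fixed":
        return m
    if spec.family == "beta":
        s = spec.sd
        nu = m * (1.0 - m) / (s * s) - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if spec.family == "normal_bounded":
        s = spec.sd if spec.sd is not None else 0.1 * m
        lo = spec.lower if spec.lower is not None else 0.75 * m
        hi = spec.upper if spec.upper is not None else 1.25 * m
        while True:
            x = float(rng.normal(m, s))
            if lo <= x <= hi:
                return x
    if spec.family == "log_normal":
        s = spec.sd if spec.sd is not None else 0.1 * m
        sigma2 = math.log(1.0 + (s / m) ** 2)
        return float(rng.lognormal(math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)))
    if spec.family == "uniform":
        return float(rng.uniform(spec.lower, spec.upper))
    if spec.family == "truncated_normal":
        lo = spec.lower if spec.lower is not None else 1.0
        while True:
            x = float(rng.normal(m, spec.sd))
            if x >= lo:
                return x
    raise ValidationError(f"unknown family {spec.family!r}")  # pragma: no cover


def default_distributions(
    params: ModelParameters,
    future_diagnosis_halfwidth: float = 0.02,
    undiagnosed_multiplier_bounds: tuple[float, float] = (1.0, 1.2),
) -> dict[str, DistributionSpec]:
    """The published distributional assumptions, in the fixed draw order.

    Annual health-service costs are specified on the pre-inflation scale;
    :func:`run_psa` inflates each draw after sampling.  The no-FASD annual
    cost and the accuracy of diagnostic testing are not varied.
    """
    t = params.tool
    c = params.costs
    if c.basis != "pre_inflation":
        raise ValidationError(
            "probabilistic analysis varies costs on the pre-inflation scale; "
            "configure costs with basis 'pre_inflation'"
        )
    m = params.mortality
    rho = params.future_diagnosis_rate
    specs = {
        "prevalence": DistributionSpec(
            "beta", params.prevalence, params.prevalence_sd, name="prevalence"
        ),
        "sensitivity": DistributionSpec(
            "beta", t.sensitivity, t.sensitivity_sd, name="sensitivity"
        ),
        "specificity": DistributionSpec(
            "beta", t.specificity, t.specificity_sd, name="specificity"
        ),
        "screening_cost": DistributionSpec(
            "normal_bounded", t.unit_cost, t.unit_cost_sd, name="screening_cost"
        ),
        "diagnostic_testing_cost": DistributionSpec(
            "normal_bounded",
            c.diagnostic_testing,
            c.diagnostic_testing_sd,
            name="diagnostic_testing_cost",
        ),
        "first_year_cost": DistributionSpec(
            "log_normal", c.first_year, c.first_year_sd, name="first_year_cost"
        ),
        "diagnosed_annual_cost": DistributionSpec(
            "log_normal",
            c.diagnosed_annual,
            c.diagnosed_annual_sd,
            name="diagnosed_annual_cost",
        ),
        "psych_diagnosed_rate": DistributionSpec(
            "beta",
            params.psych_diagnosed_rate,
            params.psych_diagnosed_rate_sd,
            name="psych_diagnosed_rate",
        ),
        "psych_undiagnosed_rate": DistributionSpec(
            "beta",
            params.psych_undiagnosed_rate,
            params.psych_undiagnosed_rate_sd,
            name="psych_undiagnosed_rate",
        ),
        "future_diagnosis_rate": DistributionSpec(
            "uniform",
            rho,
            lower=rho - future_diagnosis_halfwidth,
            upper=rho + future_diagnosis_halfwidth,
            name="future_diagnosis_rate",
        ),
        "undiagnosed_multiplier": DistributionSpec(
            "uniform",
            m.undiagnosed_multiplier,
            lower=undiagnosed_multiplier_bounds[0],
            upper=undiagnosed_multiplier_bounds[1],
            name="undiagnosed_multiplier",
        ),
        "smr_diagnosed": DistributionSpec(
            "truncated_normal",
            m.smr_diagnosed,
            m.smr_diagnosed_sd,
            lower=1.0,
            name="smr_diagnosed",
        ),
        "smr_no_fasd": DistributionSpec(
            "truncated_normal",
            m.smr_no_fasd,
            m.smr_no_fasd_sd,
            lower=1.0,
            name="smr_no_fasd",
        ),
    }
    return specs


def _apply_draw(params: ModelParameters, draw: Mapping[str, float]) -> ModelParameters:
    """Rebuild a parameter set from one vector of sampled values."""
    rec = ServiceRecommendation(
        diagnosed_psych_rate=draw["psych_diagnosed_rate"],
        undiagnosed_psych_rate=draw["psych_undiagnosed_rate"],
        psych_cost_share=params.psych_cost_share,
    )
    undiag = undiagnosed_annual_cost(draw["diagnosed_annual_cost"], rec)
    tool = dataclasses.replace(
        params.tool,
        sensitivity=draw["sensitivity"],
        specificity=draw["specificity"],
        unit_cost=draw["screening_cost"],
    )
    costs = dataclasses.replace(
        params.costs,
        first_year=draw["first_year_cost"],
        diagnosed_annual=draw["diagnosed_annual_cost"],
        undiagnosed_annual=undiag,
        diagnostic_testing=draw["diagnostic_testing_cost"],
    )
    mortality = dataclasses.replace(
        params.mortality,
        smr_diagnosed=draw["smr_diagnosed"],
        undiagnosed_multiplier=draw["undiagnosed_multiplier"],
        smr_no_fasd=draw["smr_no_fasd"],
    )
    return dataclasses.replace(
        params,
        tool=tool,
        costs=costs,
        mortality=mortality,
        prevalence=draw["prevalence"],
        future_diagnosis_rate=draw["future_diagnosis_rate"],
    )


@dataclass
class PsaDraw:
    """One probabilistic draw: sampled values and resulting deltas."""

    values: dict[str, float]
    delta_cost: float
    delta_effect: float


@dataclass
class PsaResult:
    """All draws of a probabilistic analysis."""

    draws: list[PsaDraw]
    seed: int
    n_rejected: int = 0

    @property
    def delta_cost(self) -> np.ndarray:
        return np.array([d.delta_cost for d in self.draws])

    @property
    def delta_effect(self) -> np.ndarray:
        return np.array([d.delta_effect for d in self.draws])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.draws:
            row = dict(d.values)
            row["delta_cost"] = d.delta_cost
            row["delta_effect"] = d.delta_effect
            rows.append(row)
        return pd.DataFrame(rows)


def run_psa(
    params: ModelParameters,
    n_draws: int = 5000,
    seed: int = 20190101,
    life_table: LifeTable | None = None,
    distributions: Mapping[str, DistributionSpec] | None = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis.

    Every draw samples all varied parameters independently (sensitivity and
    specificity are not correlated), recomputes the undiagnosed annual cost
    from the sampled psychiatric-recommendation rates, inflates the annual
    cost draws, runs both arms and records the per-100 deltas.  Draws whose
    parameter vector fails model validation are rejected and resampled (the
    count is kept on the result).  Reproducible for a given seed.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if life_table is None:
        from .synthetic import make_life_table

        life_table = make_life_table(end_age=params.end_age)
    specs = distributions if distributions is not None else default_distributions(params)
    rng = np.random.default_rng(seed)
    draws: list[PsaDraw] = []
    rejected = 0
    while len(draws) < n_draws:
        values = {name: sample_parameter(spec, rng) for name, spec in specs.items()}
        try:
            drawn = _apply_draw(params, values)
            ref, cmp_ = run_comparison_pair(drawn, life_table, record_trace=False)
        except (ValidationError, RuntimeError) as exc:
            rejected += 1
            logger.debug("rejected PSA draw: %s", exc)
            if rejected > 100 * n_draws:  # pragma: no cover - defensive
                raise ValidationError("PSA rejection rate implausibly high") from exc
            continue
        result = compare(ref, cmp_, drawn.cohort_size)
        draws.append(
            PsaDraw(
                values=values,
                delta_cost=result.delta_cost,
                delta_effect=result.delta_effect,
            )
        )
    if rejected:
        logger.info("PSA: %d draw(s) rejected and resampled", rejected)
    return PsaResult(draws=draws, seed=seed, n_rejected=rejected)


# ---------------------------------------------------------------------------
# Acceptability
# ---------------------------------------------------------------------------


@dataclass
class CeacPoint:
    """Probability that screening is cost-effective at one WTA threshold."""

    wta: float
    probability: float


def _acceptable(dc: np.ndarray, de: np.ndarray, wta: float) -> np.ndarray:
    """Acceptability of each draw at a WTA threshold.

    South-west draws (cost saving, diagnosed years forgone) are acceptable
    when the savings per year forgone reach the threshold:
    ``dc / de >= wta``.  Draws where screening is dominant (no effect loss,
    no extra cost) are always acceptable; dominated draws never.  A
    north-east draw (more cost, more effect -- rare here) is judged on the
    willingness-to-pay side, ``dc / de <= wta``.
    """
    acc = np.zeros(len(dc), dtype=bool)
    sw = (de < 0) & (dc < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(de != 0, dc / de, np.nan)
    acc[sw] = ratio[sw] >= wta
    dominant = (de >= 0) & (dc <= 0) & ((de > 0) | (dc < 0))
    acc[dominant] = True
    acc[(de == 0) & (dc == 0)] = True
    ne = (de > 0) & (dc > 0)
    acc[ne] = ratio[ne] <= wta
    # de < 0 with dc >= 0 (dominated): never acceptable -- already False.
    return acc


def ceac(
    psa: PsaResult | Sequence[tuple[float, float]],
    wta_grid: Sequence[float],
) -> list[CeacPoint]:
    """Cost-effectiveness acceptability curve over a WTA grid.

    For each threshold the probability is the fraction of draws acceptable
    under the WTA rule of :func:`_acceptable`.  For a pure south-west draw
    cloud the curve is monotone non-increasing in the threshold.
    """
    if isinstance(psa, PsaResult):
        dc, de = psa.delta_cost, psa.delta_effect
    else:
        arr = np.asarray(list(psa), dtype=float)
        if arr.size == 0:
            raise ValidationError("ceac: need at least one draw")
        dc, de = arr[:, 0], arr[:, 1]
    if len(dc) == 0:
        raise ValidationError("ceac: need at least one draw")
    return [
        CeacPoint(wta=float(w), probability=float(_acceptable(dc, de, w).mean()))
        for w in wta_grid
    ]


def cep_quadrant_counts(
    psa: PsaResult,
) -> dict[str, int]:
    """Cost-effectiveness-plane quadrant counts; they sum to the draw count."""
    counts = {"NE": 0, "NW": 0, "SE": 0, "SW": 0, "on-axis": 0}
    for d in psa.draws:
        counts[classify_quadrant(d.delta_cost, d.delta_effect)] += 1
    return counts


# ---------------------------------------------------------------------------
# One-way (tornado) analysis
# ---------------------------------------------------------------------------


def _cap_proportion(p: float) -> float:
    # Varied proportions are capped at 0.99 (not 1.0) so that the screen and
    # no-screen arms never coincide exactly, which would leave the ICER
    # undefined; consistent with the extreme-proportion cap used in pooling.
    return min(p, 0.99)


def _set_sensitivity(p: ModelParameters, v: float) -> ModelParameters:
    return dataclasses.replace(
        p, tool=dataclasses.replace(p.tool, sensitivity=_cap_proportion(v))
    )


def _set_specificity(p: ModelParameters, v: float) -> ModelParameters:
    return dataclasses.replace(
        p, tool=dataclasses.replace(p.tool, specificity=_cap_proportion(v))
    )


def _set_screening_cost(p: ModelParameters, v: float) -> ModelParameters:
    return dataclasses.replace(p, tool=dataclasses.replace(p.tool, unit_cost=v))


def _set_cost(field_name: str) -> Callable[[ModelParameters, float], ModelParameters]:
    def setter(p: ModelParameters, v: float) -> ModelParameters:
        return dataclasses.replace(
            p, costs=dataclasses.replace(p.costs, **{field_name: v})
        )

    return setter


def _set_smr_diagnosed(p: ModelParameters, v: float) -> ModelParameters:
    return dataclasses.replace(
        p, mortality=dataclasses.replace(p.mortality, smr_diagnosed=v)
    )


_ONE_WAY_SETTERS: dict[str, tuple[Callable[[ModelParameters], float], Callable[[ModelParameters, float], ModelParameters]]] = {
    "sensitivity": (lambda p: p.tool.sensitivity, _set_sensitivity),
    "specificity": (lambda p: p.tool.specificity, _set_specificity),
    "diagnostic_test_sensitivity": (
        lambda p: p.diagnostic_test_sensitivity,
        lambda p, v: dataclasses.replace(
            p, diagnostic_test_sensitivity=_cap_proportion(v)
        ),
    ),
    "prevalence": (
        lambda p: p.prevalence,
        lambda p, v: dataclasses.replace(p, prevalence=_cap_proportion(v)),
    ),
    "diagnosed_annual_cost": (
        lambda p: p.costs.diagnosed_annual,
        _set_cost("diagnosed_annual"),
    ),
    "undiagnosed_annual_cost": (
        lambda p: p.costs.undiagnosed_annual,
        _set_cost("undiagnosed_annual"),
    ),
    "first_year_cost": (lambda p: p.costs.first_year, _set_cost("first_year")),
    "no_fasd_annual_cost": (
        lambda p: p.costs.no_fasd_annual,
        _set_cost("no_fasd_annual"),
    ),
    "diagnostic_testing_cost": (
        lambda p: p.costs.diagnostic_testing,
        _set_cost("diagnostic_testing"),
    ),
    "screening_cost": (lambda p: p.tool.unit_cost, _set_screening_cost),
    "future_diagnosis_rate": (
        lambda p: p.future_diagnosis_rate,
        lambda p, v: dataclasses.replace(p, future_diagnosis_rate=_cap_proportion(v)),
    ),
    "smr_diagnosed": (lambda p: p.mortality.smr_diagnosed, _set_smr_diagnosed),
}

#: Parameters entering the default tornado, mirroring the published one-way
#: analysis: tool accuracy, diagnostic-test sensitivity, the share of
#: positive cases, the annual and one-off costs, the future-diagnosis rate
#: and mortality.
ONE_WAY_PARAMETERS: tuple[str, ...] = (
    "sensitivity",
    "specificity",
    "diagnostic_test_sensitivity",
    "prevalence",
    "diagnosed_annual_cost",
    "undiagnosed_annual_cost",
    "diagnostic_testing_cost",
    "screening_cost",
    "future_diagnosis_rate",
    "smr_diagnosed",
)


@dataclass
class TornadoEntry:
    """ICER swing from varying one parameter by a fixed relative amount."""

    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    range: float


def _deterministic_icer(
    params: ModelParameters, life_table: LifeTable | None
) -> IcerResult:
    ref, cmp_ = run_comparison_pair(params, life_table, record_trace=False)
    return compare(ref, cmp_, params.cohort_size)


def one_way(
    params: ModelParameters,
    parameters: Sequence[str] | None = None,
    life_table: LifeTable | None = None,
    rel: float = 0.25,
) -> list[TornadoEntry]:
    """Tornado analysis: rerun the comparison at 0.75x and 1.25x per parameter.

    Each named parameter is varied to ``(1 - rel)`` and ``(1 + rel)`` times
    its base value (proportions capped at 0.99), all else held at base case;
    entries are sorted by the ICER swing, descending.  Deterministic and
    independent of any PSA seed.
    """
    if life_table is None:
        from .synthetic import make_life_table

        life_table = make_life_table(end_age=params.end_age)
    names = tuple(parameters) if parameters is not None else ONE_WAY_PARAMETERS
    entries = []
    for name in names:
        if name not in _ONE_WAY_SETTERS:
            raise ValidationError(f"one_way: unknown parameter {name!r}")
        getter, setter = _ONE_WAY_SETTERS[name]
        base = getter(params)
        low_v, high_v = base * (1.0 - rel), base * (1.0 + rel)
        icer_low = _deterministic_icer(setter(params, low_v), life_table).icer
        icer_high = _deterministic_icer(setter(params, high_v), life_table).icer
        if icer_low is None or icer_high is None:
            swing = math.inf
        else:
            swing = abs(icer_high - icer_low)
        entries.append(
            TornadoEntry(
                parameter=name,
                low=low_v,
                high=high_v,
                icer_low=icer_low,
                icer_high=icer_high,
                range=swing,
            )
        )
    entries.sort(key=lambda e: e.range, reverse=True)
    return entries


def discount_scenarios(
    params: ModelParameters,
    rates: Sequence[float],
    life_table: LifeTable | None = None,
) -> list[tuple[float, IcerResult]]:
    """Deterministic ICER per alternative annual discount rate."""
    if life_table is None:
        from .synthetic import make_life_table

        life_table = make_life_table(end_age=params.end_age)
    out = []
    for r in rates:
        scen = dataclasses.replace(params, discount_rate=r)
        out.append((float(r), _deterministic_icer(scen, life_table)))
    return out
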