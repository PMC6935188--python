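"""Model inputs: parameter containers, configuration loading, inflation.

All monetary quantities are 2017 Canadian dollars.  The annual
health-service costs are published on two scales -- the values originally
extracted from the costing literature ("pre-inflation") and the same values
after adjustment to 2017 dollars.  The inflation factor connecting the two
scales is stored as an ordinary parameter (default derived from the three
published pre/post pairs, about 1.2685) rather than looked up from a CPI
series, and every cost is normalized to the inflated 2017 scale before
modelling.
"""

from __future__ import annotations

import dataclasses
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "ValidationError",
    "ToolProfile",
    "CostSet",
    "MortalityParams",
    "ModelParameters",
    "load_parameters",
    "base_config",
    "inflate",
    "derive_inflation_factor",
]


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or has unknown keys."""


class ValidationError(ValueError):
    """Raised when a parameter value is outside its admissible range."""


def _check(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {message}")


def _check_proportion(value: float, name: str) -> None:
    _check(0.0 <= value <= 1.0, name, f"must lie in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ToolProfile:
    """A screening tool: accuracy, unit cost and timing.

    ``screen_age`` is the age (years) at which the tool is administered and
    ``lag_to_testing`` the delay until a positive screen leads to diagnostic
    testing.  Meconium FAEE testing is applied at birth with a five-year lag
    (newborns rarely proceed to diagnostic testing immediately); the NST is
    applied at age five with no lag.
    """

    name: str
    sensitivity: float
    specificity: float
    unit_cost: float
    screen_age: int
    lag_to_testing: int
    sensitivity_sd: float | None = None
    specificity_sd: float | None = None
    unit_cost_sd: float | None = None

    def __post_init__(self) -> None:
        _check_proportion(self.sensitivity, "tool.sensitivity")
        _check_proportion(self.specificity, "tool.specificity")
        _check(self.unit_cost >= 0, "tool.unit_cost", "must be >= 0")
        _check(self.screen_age >= 0, "tool.screen_age", "must be >= 0")
        _check(self.lag_to_testing >= 0, "tool.lag_to_testing", "must be >= 0")

    @property
    def testing_age(self) -> int:
        return self.screen_age + self.lag_to_testing


@dataclass
class CostSet:
    """Annual and one-off costs on a declared basis.

    ``basis`` is ``"pre_inflation"`` for the values as extracted from the
    costing literature or ``"inflated_2017"`` after adjustment to 2017 CAD.
    The screening and diagnostic-testing costs are already 2017 dollars and
    are never rescaled; only the annual health-service costs carry the basis.
    """

    first_year: float
    diagnosed_annual: float
    undiagnosed_annual: float
    no_fasd_annual: float
    diagnostic_testing: float
    basis: str = "pre_inflation"
    first_year_sd: float | None = None
    diagnosed_annual_sd: float | None = None
    diagnostic_testing_sd: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "first_year",
            "diagnosed_annual",
            "undiagnosed_annual",
            "no_fasd_annual",
            "diagnostic_testing",
        ):
            _check(getattr(self, name) >= 0, f"costs.{name}", "must be >= 0")
        _check(
            self.basis in ("pre_inflation", "inflated_2017"),
            "costs.basis",
            f"must be 'pre_inflation' or 'inflated_2017', got {self.basis!r}",
        )
        if self.basis == "inflated_2017":
            # The undiagnosed cost is derived from sampled recommendation
            # rates in probabilistic analysis and may legitimately exceed the
            # diagnosed cost in a draw, so only the first-year dominance is a
            # hard invariant.
            _check(
                self.first_year >= self.diagnosed_annual
                and self.first_year >= self.undiagnosed_annual,
                "costs",
                "on the inflated basis the first-year cost must dominate the "
                "annual state costs",
            )

    def inflated(self, factor: float, inflate_no_fasd: bool = True) -> "CostSet":
        """Return this cost set normalized to the inflated 2017 basis.

        Only the annual health-service costs are rescaled.  Whether the
        no-FASD annual cost participates is a modelling switch: the published
        table marks it "not varied" and it is unclear whether it was already
        expressed in 2017 dollars.
        """
        if self.basis == "inflated_2017":
            return self
        return dataclasses.replace(
            self,
            first_year=inflate(self.first_year, factor),
            diagnosed_annual=inflate(self.diagnosed_annual, factor),
            undiagnosed_annual=inflate(self.undiagnosed_annual, factor),
            no_fasd_annual=(
                inflate(self.no_fasd_annual, factor)
                if inflate_no_fasd
                else self.no_fasd_annual
            ),
            basis="inflated_2017",
        )


@dataclass
class MortalityParams:
    """Standardized mortality ratios applied on top of the background life table.

    The diagnosed-FASD SMR of 3.15 is the single published estimate for an
    FASD cohort; undiagnosed FASD is assumed 10% higher, and the no-FASD
    group (children assessed for, but not meeting, FASD criteria) is assumed
    to share the diagnosed SMR.
    """

    smr_diagnosed: float = 3.15
    undiagnosed_multiplier: float = 1.10
    smr_no_fasd: float = 3.15
    smr_diagnosed_sd: float = 1.6
    smr_no_fasd_sd: float = 2.0

    def __post_init__(self) -> None:
        _check(self.smr_diagnosed >= 0, "mortality.smr_diagnosed", "must be >= 0")
        _check(self.smr_no_fasd >= 0, "mortality.smr_no_fasd", "must be >= 0")
        _check(
            self.undiagnosed_multiplier >= 1.0,
            "mortality.undiagnosed_multiplier",
            "must be >= 1",
        )


@dataclass
class ModelParameters:
    """Complete parameter set for one screening comparison.

    ``tool`` selects the comparison: the meconium profile implies a model
    starting at birth with an 18-year horizon; the NST profile a model
    starting at age five with a 13-year horizon.  ``cost_basis`` selects the
    scale on which annual costs enter the Markov engine (the inflated 2017
    scale by default), and ``pending_fasd_cost`` which annual cost the
    FASD-positive children awaiting diagnostic testing accrue.
    """

    tool: ToolProfile
    costs: CostSet
    mortality: MortalityParams = field(default_factory=MortalityParams)
    cohort_size: float = 100.0
    prevalence: float = 0.663
    prevalence_sd: float = 0.014
    discount_rate: float = 0.015
    end_age: int = 18
    future_diagnosis_rate: float = 0.05
    inflation_factor: float = 1.26845
    # Psychiatric-care recommendation rates driving the undiagnosed cost.
    psych_diagnosed_rate: float = 0.556
    psych_diagnosed_rate_sd: float = 0.073
    psych_undiagnosed_rate: float = 0.330
    psych_undiagnosed_rate_sd: float = 0.147
    psych_cost_share: float | None = None
    # Modelling switches.
    diagnostic_test_sensitivity: float = 1.0
    cost_basis: str = "inflated_2017"
    pending_fasd_cost: str = "undiagnosed"
    half_cycle: str = "mid_cycle"
    inflate_no_fasd: bool = True

    def __post_init__(self) -> None:
        _check(self.cohort_size > 0, "cohort.size", "must be > 0")
        _check(
            0.0 < self.prevalence < 1.0,
            "cohort.prevalence",
            f"must lie in (0, 1), got {self.prevalence!r}",
        )
        _check(self.discount_rate >= 0, "time.discount_rate", "must be >= 0")
        _check(self.end_age > 0, "time.end_age", "must be > 0")
        _check_proportion(self.future_diagnosis_rate, "model.future_diagnosis_rate")
        _check(self.inflation_factor > 0, "costs.inflation_factor", "must be > 0")
        _check_proportion(
            self.diagnostic_test_sensitivity, "model.diagnostic_test_sensitivity"
        )
        _check_proportion(self.psych_diagnosed_rate, "costs.psych_diagnosed_rate")
        _check_proportion(self.psych_undiagnosed_rate, "costs.psych_undiagnosed_rate")
        _check(
            self.cost_basis in ("pre_inflation", "inflated_2017"),
            "model.cost_basis",
            f"must be 'pre_inflation' or 'inflated_2017', got {self.cost_basis!r}",
        )
        _check(
            self.pending_fasd_cost in ("undiagnosed", "no_fasd", "diagnosed"),
            "model.pending_fasd_cost",
            f"unrecognized choice {self.pending_fasd_cost!r}",
        )
        _check(
            self.half_cycle in ("mid_cycle", "trapezoidal"),
            "time.half_cycle",
            f"must be 'mid_cycle' or 'trapezoidal', got {self.half_cycle!r}",
        )
        _check(
            self.end_age > self.tool.testing_age,
            "time.end_age",
            "horizon must extend beyond the diagnostic-testing age",
        )

    def effective_costs(self) -> CostSet:
        """Costs on the basis the Markov engine runs on (``cost_basis``)."""
        if self.cost_basis == "inflated_2017":
            return self.costs.inflated(self.inflation_factor, self.inflate_no_fasd)
        if self.costs.basis != "pre_inflation":
            raise ValidationError(
                "model.cost_basis: cannot run on the pre-inflation basis from "
                "costs already expressed in 2017 dollars"
            )
        return self.costs

    def to_config(self) -> dict[str, Any]:
        """Serialize to a configuration mapping (single-tool form)."""
        t = self.tool
        c = self.costs
        m = self.mortality
        return {
            "cohort": {
                "size": self.cohort_size,
                "prevalence": self.prevalence,
                "prevalence_sd": self.prevalence_sd,
            },
            "tools": {
                t.name: {
                    "sensitivity": t.sensitivity,
                    "sensitivity_sd": t.sensitivity_sd,
                    "specificity": t.specificity,
                    "specificity_sd": t.specificity_sd,
                    "unit_cost": t.unit_cost,
                    "unit_cost_sd": t.unit_cost_sd,
                    "screen_age": t.screen_age,
                    "lag_to_testing": t.lag_to_testing,
                }
            },
            "costs": {
                "basis": c.basis,
                "first_year": c.first_year,
                "first_year_sd": c.first_year_sd,
                "diagnosed_annual": c.diagnosed_annual,
                "diagnosed_annual_sd": c.diagnosed_annual_sd,
                "undiagnosed_annual": c.undiagnosed_annual,
                "no_fasd_annual": c.no_fasd_annual,
                "diagnostic_testing": c.diagnostic_testing,
                "diagnostic_testing_sd": c.diagnostic_testing_sd,
                "inflation_factor": self.inflation_factor,
                "inflate_no_fasd": self.inflate_no_fasd,
                "psych_diagnosed_rate": self.psych_diagnosed_rate,
                "psych_diagnosed_rate_sd": self.psych_diagnosed_rate_sd,
                "psych_undiagnosed_rate": self.psych_undiagnosed_rate,
                "psych_undiagnosed_rate_sd": self.psych_undiagnosed_rate_sd,
                "psych_cost_share": self.psych_cost_share,
            },
            "mortality": {
                "smr_diagnosed": m.smr_diagnosed,
                "smr_diagnosed_sd": m.smr_diagnosed_sd,
                "undiagnosed_multiplier": m.undiagnosed_multiplier,
                "smr_no_fasd": m.smr_no_fasd,
                "smr_no_fasd_sd": m.smr_no_fasd_sd,
            },
            "time": {
                "end_age": self.end_age,
                "discount_rate": self.discount_rate,
                "half_cycle": self.half_cycle,
            },
            "model": {
                "future_diagnosis_rate": self.future_diagnosis_rate,
                "diagnostic_test_sensitivity": self.diagnostic_test_sensitivity,
                "cost_basis": self.cost_basis,
                "pending_fasd_cost": self.pending_fasd_cost,
            },
        }


# ---------------------------------------------------------------------------
# Inflation
# ---------------------------------------------------------------------------


def inflate(cost_pre: float, factor: float) -> float:
    """Rescale a pre-inflation cost to 2017 dollars.

    Full precision is kept; rounding to the cent happens only in reports.
    """
    if cost_pre < 0:
        raise ValidationError(f"inflate: cost must be >= 0, got {cost_pre!r}")
    if factor <= 0:
        raise ValidationError(f"inflate: factor must be > 0, got {factor!r}")
    return cost_pre * factor


def derive_inflation_factor(pairs: Sequence[tuple[float, float]]) -> float:
    """Least-squares inflation factor from (pre, post) cost pairs.

    Minimizes ``sum((post - f * pre)^2)`` giving ``f = sum(pre * post) /
    sum(pre^2)``.  Pairs whose individual ratios disagree by more than 1%
    trigger a warning but not a failure.
    """
    if not pairs:
        raise ValidationError("derive_inflation_factor: need at least one pair")
    for pre, post in pairs:
        if pre <= 0 or post <= 0:
            raise ValidationError(
                f"derive_inflation_factor: pairs must be positive, got {(pre, post)!r}"
            )
    ratios = [post / pre for pre, post in pairs]
    if max(ratios) / min(ratios) > 1.01:
        warnings.warn(
            "inflation pairs disagree by more than 1%: ratios "
            + ", ".join(f"{r:.5f}" for r in ratios),
            stacklevel=2,
        )
    num = sum(pre * post for pre, post in pairs)
    den = sum(pre * pre for pre, _ in pairs)
    return num / den


#: The three annual health-service costs published on both scales.
PUBLISHED_COST_PAIRS: tuple[tuple[float, float], ...] = (
    (3426.0, 4346.0),   # diagnosed FASD, annual
    (15976.0, 20265.0), # first year of life
    (2713.0, 3441.0),   # undiagnosed FASD, annual
)


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------

_BASE_CONFIG: dict[str, Any] = {
    "cohort": {"size": 100.0, "prevalence": 0.663, "prevalence_sd": 0.014},
    "tools": {
        "meconium": {
            "sensitivity": 0.924,
            "sensitivity_sd": 0.081,
            "specificity": 0.515,
            "specificity_sd": 0.197,
            "unit_cost": 175.0,
            "unit_cost_sd": 18.0,
            "screen_age": 0,
            "lag_to_testing": 5,
        },
        "nst": {
            "sensitivity": 0.859,
            "sensitivity_sd": 0.055,
            "specificity": 0.729,
            "specificity_sd": 0.107,
            "unit_cost": 20.0,
            "unit_cost_sd": 2.0,
            "screen_age": 5,
            "lag_to_testing": 0,
        },
    },
    "costs": {
        "basis": "pre_inflation",
        "first_year": 15976.0,
        "first_year_sd": 1598.0,
        "diagnosed_annual": 3426.0,
        "diagnosed_annual_sd": 343.0,
        "undiagnosed_annual": 2713.0,
        "no_fasd_annual": 3101.0,
        "diagnostic_testing": 3870.0,
        "diagnostic_testing_sd": 387.0,
        "inflation_factor": None,  # None -> derived from the published pairs
        "inflate_no_fasd": True,
        "psych_diagnosed_rate": 0.556,
        "psych_diagnosed_rate_sd": 0.073,
        "psych_undiagnosed_rate": 0.330,
        "psych_undiagnosed_rate_sd": 0.147,
        "psych_cost_share": None,  # None -> calibrated from the cost anchors
    },
    "mortality": {
        "smr_diagnosed": 3.15,
        "smr_diagnosed_sd": 1.6,
        "undiagnosed_multiplier": 1.10,
        "smr_no_fasd": 3.15,
        "smr_no_fasd_sd": 2.0,
    },
    "time": {"end_age": 18, "discount_rate": 0.015, "half_cycle": "mid_cycle"},
    "model": {
        "future_diagnosis_rate": 0.05,
        "diagnostic_test_sensitivity": 1.0,
        "cost_basis": "inflated_2017",
        "pending_fasd_cost": "undiagnosed",
    },
    "psa": {
        "n_draws": 5000,
        "seed": 20190101,
        "future_diagnosis_halfwidth": 0.02,
        "undiagnosed_multiplier_low": 1.0,
        "undiagnosed_multiplier_high": 1.2,
    },
}


def base_config() -> dict[str, Any]:
    """A deep copy of the built-in base-case configuration."""
    import copy

    return copy.deepcopy(_BASE_CONFIG)


def _merge_checked(base: Mapping[str, Any], override: Mapping[str, Any], path: str) -> dict[str, Any]:
    """Deep-merge ``override`` onto ``base``, rejecting unknown keys by name."""
    merged = dict(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown configuration key: {where!r}")
        if isinstance(base[key], Mapping):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{where!r} must be a mapping")
            merged[key] = _merge_checked(base[key], value, where)
        else:
            merged[key] = value
    return merged


def _parse_source(source: Any) -> dict[str, Any]:
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    if isinstance(source, io.IOBase):
        text = source.read()
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        text = path.read_text()
    try:
        parsed = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"could not parse configuration{line}: {exc}") from exc
    if parsed is None:
        return {}
    if not isinstance(parsed, Mapping):
        raise ConfigError("configuration root must be a mapping")
    return dict(parsed)


def load_parameters(
    source: Any = None,
    comparison: str = "meconium",
    overrides: Mapping[str, Any] | None = None,
) -> ModelParameters:
    """Build a validated :class:`ModelParameters` for one comparison.

    ``source`` may be a path to a YAML/JSON configuration file, an open
    stream, a mapping, or ``None`` for the built-in base case.  Omitted keys
    take their base-case defaults; unknown keys raise :class:`ConfigError`
    naming the offending key.  ``comparison`` selects which tool profile
    ("meconium" or "nst") the returned parameter set carries.
    """
    if comparison not in ("meconium", "nst"):
        raise ConfigError(f"unknown comparison {comparison!r}; use 'meconium' or 'nst'")
    cfg = _merge_checked(_BASE_CONFIG, _parse_source(source), "")
    if overrides:
        cfg = _merge_checked(cfg, overrides, "")

    tools_cfg = cfg["tools"]
    if comparison not in tools_cfg:
        raise ConfigError(f"tools: no profile for comparison {comparison!r}")
    tool_cfg = _merge_checked(
        _BASE_CONFIG["tools"][comparison], tools_cfg[comparison], f"tools.{comparison}"
    )
    tool = ToolProfile(name=comparison, **tool_cfg)

    c = cfg["costs"]
    costs = CostSet(
        first_year=float(c["first_year"]),
        diagnosed_annual=float(c["diagnosed_annual"]),
        undiagnosed_annual=float(c["undiagnosed_annual"]),
        no_fasd_annual=float(c["no_fasd_annual"]),
        diagnostic_testing=float(c["diagnostic_testing"]),
        basis=c["basis"],
        first_year_sd=c["first_year_sd"],
        diagnosed_annual_sd=c["diagnosed_annual_sd"],
        diagnostic_testing_sd=c["diagnostic_testing_sd"],
    )
    m = cfg["mortality"]
    mortality = MortalityParams(
        smr_diagnosed=float(m["smr_diagnosed"]),
        undiagnosed_multiplier=float(m["undiagnosed_multiplier"]),
        smr_no_fasd=float(m["smr_no_fasd"]),
        smr_diagnosed_sd=float(m["smr_diagnosed_sd"]),
        smr_no_fasd_sd=float(m["smr_no_fasd_sd"]),
    )
    factor = c["inflation_factor"]
    if factor is None:
        factor = derive_inflation_factor(PUBLISHED_COST_PAIRS)
    return ModelParameters(
        tool=tool,
        costs=costs,
        mortality=mortality,
        cohort_size=float(cfg["cohort"]["size"]),
        prevalence=float(cfg["cohort"]["prevalence"]),
        prevalence_sd=float(cfg["cohort"]["prevalence_sd"]),
        discount_rate=float(cfg["time"]["discount_rate"]),
        end_age=int(cfg["time"]["end_age"]),
        half_cycle=cfg["time"]["half_cycle"],
        future_diagnosis_rate=float(cfg["model"]["future_diagnosis_rate"]),
        inflation_factor=float(factor),
        psych_diagnosed_rate=float(c["psych_diagnosed_rate"]),
        psych_diagnosed_rate_sd=float(c["psych_diagnosed_rate_sd"]),
        psych_undiagnosed_rate=float(c["psych_undiagnosed_rate"]),
        psych_undiagnosed_rate_sd=float(c["psych_undiagnosed_rate_sd"]),
        psych_cost_share=c["psych_cost_share"],
        diagnostic_test_sensitivity=float(cfg["model"]["diagnostic_test_sensitivity"]),
        cost_basis=cfg["model"]["cost_basis"],
        pending_fasd_cost=cfg["model"]["pending_fasd_cost"],
        inflate_no_fasd=bool(c["inflate_no_fasd"]),
    )
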