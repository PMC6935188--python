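"""Random-effects pooling of screening-tool diagnostic accuracy.

Study-level sensitivities and specificities are pooled with the
DerSimonian-Laird moment estimator directly on the proportion scale.
Studies that report no dispersion get a standard deviation imputed from the
beta-distribution variance formula ``sqrt(p * (1 - p) / (n + 1))``, where
``n`` is the number of subjects behind the proportion (positive cases for a
sensitivity, controls for a specificity).  Proportions of exactly 0 or 1 are
first capped to 0.01 / 0.99, since the beta formula would otherwise give a
zero variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .parameters import ValidationError

__all__ = [
    "AccuracyStudy",
    "PooledAccuracy",
    "cap_extreme",
    "beta_sd",
    "impute_sd",
    "pool_random_effects",
    "load_studies",
    "bundled_table_path",
    "pool_table",
]


@dataclass
class AccuracyStudy:
    """One study's estimate of a single accuracy proportion."""

    label: str
    proportion: float
    group_n: int
    sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValidationError(
                f"study {self.label!r}: proportion must lie in [0, 1]"
            )
        if self.group_n < 1:
            raise ValidationError(f"study {self.label!r}: group_n must be >= 1")
        if self.sd is not None and not 0.0 < self.sd < 1.0:
            raise ValidationError(f"study {self.label!r}: sd must lie in (0, 1)")


@dataclass
class PooledAccuracy:
    """Pooled mean with between-study dispersion.

    ``pooled_sd`` is the between-study standard deviation ``sqrt(tau2)``.
    """

    mean: float
    between_study_variance: float
    pooled_sd: float
    k: int


def cap_extreme(p: float) -> float:
    """Cap a degenerate proportion: 1.0 becomes 0.99 and 0.0 becomes 0.01.

    A proportion of exactly 0 or 1 has zero beta-distribution variance, so
    perfect study results are nudged one percentage point inward before
    dispersion is imputed.
    """
    if p == 1.0:
        return 0.99
    if p == 0.0:
        return 0.01
    return p


def beta_sd(p: float, n: int) -> float:
    """Standard deviation imputed from the beta-distribution variance formula.

    For a proportion ``p`` observed on ``n`` subjects the imputed variance is
    ``p * (1 - p) / (n + 1)``, the variance of a Beta(n*p, n*(1-p))
    distribution.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(
            f"beta_sd: p must lie strictly in (0, 1); cap extremes first (got {p!r})"
        )
    if n < 1:
        raise ValidationError(f"beta_sd: n must be >= 1, got {n!r}")
    return math.sqrt(p * (1.0 - p) / (n + 1.0))


def impute_sd(study: AccuracyStudy) -> float:
    """The study's SD, imputing via :func:`beta_sd` when it is missing."""
    if study.sd is not None:
        return study.sd
    return beta_sd(cap_extreme(study.proportion), study.group_n)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def pool_random_effects(
    studies: Sequence[AccuracyStudy],
    scale: str = "proportion",
    tau2_override: float | None = None,
) -> PooledAccuracy:
    """DerSimonian-Laird random-effects pooling of accuracy proportions.

    On the default proportion scale the estimator is: fixed-effect weights
    ``w_i = 1 / sd_i**2``; heterogeneity ``Q = sum(w_i * (p_i - mu_FE)**2)``;
    ``tau2 = max(0, (Q - (k - 1)) / (sum(w) - sum(w**2) / sum(w)))``; and
    random-effects weights ``w*_i = 1 / (sd_i**2 + tau2)`` giving the pooled
    mean.  ``scale="logit"`` applies the same estimator to logit-transformed
    proportions (delta-method variances) and back-transforms the mean; the
    proportion scale is the default because it reproduces the published
    pooled accuracies.  ``tau2_override`` substitutes a fixed between-study
    variance (used to probe the equal-weight limit).
    """
    if scale not in ("proportion", "logit"):
        raise ValidationError(f"pool_random_effects: unknown scale {scale!r}")
    if not studies:
        raise ValidationError("pool_random_effects: need at least one study")
    p = [cap_extreme(s.proportion) for s in studies]
    sd = [impute_sd(s) for s in studies]
    if any(v <= 0 for v in sd):
        raise ValidationError(
            "pool_random_effects: zero study SD; cap extreme proportions first"
        )
    if scale == "logit":
        var = [(s / (q * (1.0 - q))) ** 2 for q, s in zip(p, sd)]
        y = [_logit(q) for q in p]
    else:
        var = [s * s for s in sd]
        y = list(p)
    k = len(studies)
    if k == 1:
        tau2 = 0.0 if tau2_override is None else tau2_override
        mean = y[0]
    else:
        w = [1.0 / v for v in var]
        sw = sum(w)
        mu_fe = sum(wi * yi for wi, yi in zip(w, y)) / sw
        q_stat = sum(wi * (yi - mu_fe) ** 2 for wi, yi in zip(w, y))
        denom = sw - sum(wi * wi for wi in w) / sw
        tau2 = max(0.0, (q_stat - (k - 1)) / denom)
        if tau2_override is not None:
            tau2 = tau2_override
        w_re = [1.0 / (v + tau2) for v in var]
        mean = sum(wi * yi for wi, yi in zip(w_re, y)) / sum(w_re)
    if scale == "logit":
        mean = _inv_logit(mean)
    return PooledAccuracy(
        mean=mean,
        between_study_variance=tau2,
        pooled_sd=math.sqrt(tau2),
        k=k,
    )


# ---------------------------------------------------------------------------
# Bundled study tables
# ---------------------------------------------------------------------------

_TABLES = {"meconium": "table1_meconium.csv", "nst": "table2_nst.csv"}


def bundled_table_path(which: str) -> Path:
    """Path to a bundled study table ("meconium" or "nst")."""
    if which not in _TABLES:
        raise ValidationError(f"no bundled table {which!r}; use 'meconium' or 'nst'")
    return Path(str(resources.files("fasdscreen").joinpath("data", _TABLES[which])))


def load_studies(path: str | Path, measure: str | None = None) -> list[AccuracyStudy]:
    """Read accuracy studies from CSV.

    Expected columns: ``label``, ``proportion``, ``group_n`` and optionally
    ``sd`` (blank for imputation) and ``measure`` ("sensitivity" or
    "specificity", filtered when ``measure`` is given).
    """
    df = pd.read_csv(path)
    required = {"label", "proportion", "group_n"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"study table {path}: missing columns {sorted(missing)}")
    if measure is not None:
        if "measure" not in df.columns:
            raise ValidationError(f"study table {path}: no 'measure' column to filter")
        df = df[df["measure"] == measure]
    studies = []
    for row in df.itertuples(index=False):
        sd = getattr(row, "sd", None)
        if sd is not None and pd.isna(sd):
            sd = None
        studies.append(
            AccuracyStudy(
                label=str(row.label),
                proportion=float(row.proportion),
                group_n=int(row.group_n),
                sd=None if sd is None else float(sd),
            )
        )
    return studies


def pool_table(which: str, scale: str = "proportion") -> dict[str, PooledAccuracy]:
    """Pool a bundled study table; returns sensitivity and specificity."""
    path = bundled_table_path(which)
    return {
        measure: pool_random_effects(load_studies(path, measure), scale=scale)
        for measure in ("sensitivity", "specificity")
    }
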