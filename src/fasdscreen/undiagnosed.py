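"""Annual cost of undiagnosed (and by extension not-yet-assessed) FASD.

Children with FASD who are missed by screening still use health services,
but chart-review evidence on children whose FASD assessment was deferred
shows they are recommended psychiatric care less often than diagnosed
children (33.0% vs 55.6%).  The undiagnosed annual cost is therefore
modelled as the diagnosed annual cost with the psychiatric-influenced share
of spending reduced in proportion to the recommendation gap:

    c_undiag = c_diag * (1 - share * (1 - rate_undiag / rate_diag))

``share`` -- the fraction of the diagnosed annual cost attributable to
psychiatric-influenced services -- is a free calibration parameter.  Its
default is back-solved so that the base-case inputs reproduce the published
pre-inflation anchor of $2713/year (share approximately 0.512); inflating
the result reproduces the published $3441 in 2017 dollars.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ValidationError

__all__ = [
    "ServiceRecommendation",
    "undiagnosed_annual_cost",
    "calibrate_psych_share",
    "DEFAULT_PSYCH_SHARE",
]


@dataclass
class ServiceRecommendation:
    """Psychiatric-care recommendation rates and the calibrated cost share."""

    diagnosed_psych_rate: float = 0.556
    undiagnosed_psych_rate: float = 0.330
    psych_cost_share: float | None = None

    def __post_init__(self) -> None:
        for name in ("diagnosed_psych_rate", "undiagnosed_psych_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.psych_cost_share is not None and not 0.0 <= self.psych_cost_share <= 1.0:
            raise ValidationError("psych_cost_share must lie in [0, 1]")


def calibrate_psych_share(
    c_diag_annual: float,
    c_undiag_annual: float,
    diagnosed_rate: float = 0.556,
    undiagnosed_rate: float = 0.330,
) -> float:
    """Back-solve the psychiatric cost share from the two cost anchors.

    Solves ``c_undiag = c_diag * (1 - share * (1 - r_u / r_d))`` for
    ``share``.  With the published base-case inputs (3426, 2713,
    0.556, 0.330) the share is approximately 0.512.
    """
    if c_diag_annual <= 0:
        raise ValidationError("diagnosed annual cost must be > 0")
    if diagnosed_rate <= 0:
        raise ValidationError("diagnosed psychiatric rate must be > 0")
    gap = 1.0 - undiagnosed_rate / diagnosed_rate
    if gap == 0.0:
        raise ValidationError("rates are equal; the share is unidentified")
    return (1.0 - c_undiag_annual / c_diag_annual) / gap


#: Share calibrated from the published anchors ($3426 diagnosed, $2713
#: undiagnosed, recommendation rates 55.6% / 33.0%).
DEFAULT_PSYCH_SHARE: float = calibrate_psych_share(3426.0, 2713.0, 0.556, 0.330)


def undiagnosed_annual_cost(
    c_diag_annual: float, rec: ServiceRecommendation
) -> float:
    """Annual cost of undiagnosed FASD from the diagnosed cost and rates.

    Uses the recommendation's ``psych_cost_share`` when set, otherwise the
    calibrated default.  The result is on the same basis (pre-inflation or
    2017 dollars) as ``c_diag_annual``.
    """
    if c_diag_annual < 0:
        raise ValidationError("diagnosed annual cost must be >= 0")
    if rec.diagnosed_psych_rate == 0.0:
        raise ValidationError("diagnosed psychiatric rate must be > 0")
    share = rec.psych_cost_share
    if share is None:
        share = DEFAULT_PSYCH_SHARE
    ratio = rec.undiagnosed_psych_rate / rec.diagnosed_psych_rate
    return c_diag_annual * (1.0 - share * (1.0 - ratio))
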