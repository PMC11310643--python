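"""Convert trial risk differences into DALYs averted.

The evaluation maps five binary trial outcomes (HIV testing, STI testing,
modern contraceptive use, no forced drinking at work, low/no gender-based
violence) onto disability-adjusted life years over a 1-year horizon.  With
no mortality pathway in the model, the DALYs attached to each outcome equal
its disability weight times time, so the per-person health effect of the
intervention for outcome ``i`` is::

    dalys_averted_i = (ARD_i / 100) * DW_i * 1 year

where ``ARD_i`` is the absolute risk difference on the percent scale
(intervention minus usual-care endline risk) and ``DW_i`` is the disability
weight of the health state the outcome protects against.  All five
outcomes are coded so that a *higher* endline "risk" is the good state
(tested, used contraception, no forced drinking, low/no violence); the
total effect is the plain sum over outcomes, and outcomes on which the
intervention underperformed contribute negatively.

The percent-to-proportion conversion (division by 100) happens in this
module and nowhere else: every upstream risk quantity is carried on the
percent scale the trial reports.
"""

from __future__ import annotations

from typing import Iterable, Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "RiskSummary",
    "WeightSummary",
    "OutcomeSpec",
    "DWAdjustment",
    "ard",
    "adjust_dw",
    "dalys_averted",
    "total_dalys_averted",
]


class RiskSummary(BaseModel):
    """Arm-level endline risk: mean in percent, SD in percentage points."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    mean: float
    sd: float

    @model_validator(mode="after")
    def _check_range(self) -> "RiskSummary":
        if not 0.0 <= self.mean <= 100.0:
            raise ValueError(f"risk mean must be in [0, 100], got {self.mean}")
        if self.sd < 0.0:
            raise ValueError(f"risk sd must be >= 0, got {self.sd}")
        return self


class WeightSummary(BaseModel):
    """Disability weight: dimensionless mean in (0, 1) with an SD.

    The SD must be feasible for a beta distribution on (0, 1), i.e.
    ``sd**2 < mean * (1 - mean)``; the probabilistic engine samples
    disability weights from a moment-matched beta.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    mean: float
    sd: float

    @model_validator(mode="after")
    def _check_moments(self) -> "WeightSummary":
        if not 0.0 < self.mean < 1.0:
            raise ValueError(
                f"disability weight mean must be in (0, 1), got {self.mean}"
            )
        if self.sd < 0.0:
            raise ValueError(f"disability weight sd must be >= 0, got {self.sd}")
        if self.sd**2 >= self.mean * (1.0 - self.mean):
            raise ValueError(
                "disability weight sd is infeasible for a beta distribution: "
                f"sd^2 = {self.sd**2:g} >= mean*(1-mean) = "
                f"{self.mean * (1.0 - self.mean):g}"
            )
        return self


class OutcomeSpec(BaseModel):
    """One trial outcome and the disability weight it maps to.

    Parameters
    ----------
    name
        Machine-friendly outcome identifier (e.g. ``"hiv_testing"``).
    label
        Human-readable outcome description; optional.
    risk_control, risk_intervention
        Endline risk summaries per arm, percent scale.
    dw
        Disability weight summary for the averted health state.
    beneficial_direction
        All supported outcomes are coded so the higher endline risk is the
        healthier state; the field is explicit so the sign convention is
        visible in configs.
    risk_control_bounds, risk_intervention_bounds
        Optional explicit (lower, upper) percent bounds, used only by the
        uniform risk family when supplied (otherwise uniform bounds are
        moment-matched).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    label: Optional[str] = None
    risk_control: RiskSummary
    risk_intervention: RiskSummary
    dw: WeightSummary
    beneficial_direction: Literal["higher_risk_is_better"] = "higher_risk_is_better"
    risk_control_bounds: Optional[Tuple[float, float]] = None
    risk_intervention_bounds: Optional[Tuple[float, float]] = None

    @model_validator(mode="after")
    def _check_bounds(self) -> "OutcomeSpec":
        for field in ("risk_control_bounds", "risk_intervention_bounds"):
            bounds = getattr(self, field)
            if bounds is not None and bounds[0] > bounds[1]:
                raise ValueError(f"{field} must be ordered, got {bounds}")
        return self


class DWAdjustment(BaseModel):
    """Generic disability-weight adjustment for care-cascade attenuation.

    Raw burden-of-disease weights describe the disease state itself; when
    the trial outcome is a screening behaviour, the realized per-person
    weight is attenuated by how common the disease is and how often a
    positive test leads to treatment.  ``mode="multiplicative"`` applies
    ``dw * prevalence * p_treated_after_positive``; ``mode="none"`` is the
    identity and is the default, because the bundled weights are already
    adjusted inputs.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    mode: Literal["none", "multiplicative"] = "none"
    prevalence: float = 1.0
    p_treated_after_positive: float = 1.0

    @model_validator(mode="after")
    def _check_props(self) -> "DWAdjustment":
        for field in ("prevalence", "p_treated_after_positive"):
            value = getattr(self, field)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{field} must be in [0, 1], got {value}")
        return self


def ard(spec: OutcomeSpec) -> float:
    """Absolute risk difference in percentage points.

    Intervention-arm endline risk minus usual-care endline risk; negative
    when the intervention underperformed on the outcome.
    """
    return spec.risk_intervention.mean - spec.risk_control.mean


def adjust_dw(dw_mean: float, adjustment: DWAdjustment) -> float:
    """Apply a :class:`DWAdjustment` to a raw disability-weight mean."""
    if adjustment.mode == "none":
        return dw_mean
    return dw_mean * adjustment.prevalence * adjustment.p_treated_after_positive


def dalys_averted(ard_pp: float, dw: float, years: float = 1.0) -> float:
    """DALYs averted per person from an ARD (percentage points) and weight.

    ``(ard_pp / 100) * dw * years``; bilinear in both arguments, and the
    sign follows the ARD.  The default 1-year horizon reflects the model's
    morbidity-only construction (no years of life lost).
    """
    return (ard_pp / 100.0) * dw * years


def total_dalys_averted(per_outcome: Iterable[float]) -> float:
    """Sum per-outcome DALYs averted (the model's total effect).

    Raises ``ValueError`` on an empty list: a total over no outcomes is a
    config error, not a zero effect.
    """
    values = list(per_outcome)
    if not values:
        raise ValueError("total_dalys_averted requires at least one outcome")
    return float(sum(values))
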