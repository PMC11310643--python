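"""Cost analysis: total, per-person, and incremental costs by perspective.

Two perspectives are supported.  The payer perspective allocates program
expenditure: costs incurred for both arms (usual-care services) are spread
evenly over all participants, while intervention-only costs are apportioned
to intervention-arm participants alone.  The combined payer+patient
perspective additionally credits each arm with the value of participant
time saved by outreach-worker contact (time valued at the earnings rate),
subtracting the per-person saving from the per-person payer cost.

Because the allocation denominators behind the published per-person costs
were never printed, per-person overrides are first-class config: when set
they take precedence over ledger allocation, and totals are reported only
when denominators are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "FUNDERS",
    "ACTIVITIES",
    "INPUT_TYPES",
    "ARM_SCOPES",
    "CostLedgerEntry",
    "CostingConfig",
    "CostSummary",
    "ledger_total",
    "allocate_payer_costs",
    "patient_time_savings",
    "combined_perspective",
]

logger = logging.getLogger(__name__)

FUNDERS = ("expertise_france", "global_fund")
ACTIVITIES = ("diagnosis_treatment", "iec", "program_management")
INPUT_TYPES = ("consumables", "personnel")
ARM_SCOPES = ("both_arms", "intervention_only")

Arm = Literal["control", "intervention"]


class CostLedgerEntry(BaseModel):
    """One expenditure line of the payer cost ledger."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    funder: Literal["expertise_france", "global_fund"]
    activity: Literal["diagnosis_treatment", "iec", "program_management"]
    input_type: Literal["consumables", "personnel"]
    amount_usd: float
    arm_scope: Literal["both_arms", "intervention_only"]

    @model_validator(mode="after")
    def _check_amount(self) -> "CostLedgerEntry":
        if self.amount_usd < 0.0:
            raise ValueError(f"amount_usd must be >= 0, got {self.amount_usd}")
        return self


class CostingConfig(BaseModel):
    """Inputs for the cost analysis.

    Either both per-person overrides or both denominators must be supplied
    for the payer allocation.  The time-cost chain values participant time
    at the earnings rate (`hourly_wage_usd`), applied to the time saved per
    outreach contact times the number of contacts, scaled by each arm's
    outreach-contact proportion.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    ledger: Optional[str] = None
    n_usual_care_denominator: Optional[int] = None
    n_intervention_denominator: Optional[int] = None
    per_person_usual_care: Optional[float] = None
    per_person_intervention: Optional[float] = None
    time_with_outreach_h: float = 0.6
    time_without_outreach_h: float = 2.2
    contacts_per_person: float = 2.0
    hourly_wage_usd: float = 6.75
    outreach_contact_rate_intervention: float = 0.585
    outreach_contact_rate_control: float = 0.400

    @model_validator(mode="after")
    def _check(self) -> "CostingConfig":
        for field in ("n_usual_care_denominator", "n_intervention_denominator"):
            value = getattr(self, field)
            if value is not None and value < 1:
                raise ValueError(f"{field} must be >= 1, got {value}")
        for field in ("time_with_outreach_h", "time_without_outreach_h",
                      "contacts_per_person", "hourly_wage_usd"):
            if getattr(self, field) < 0.0:
                raise ValueError(f"{field} must be >= 0")
        for field in ("outreach_contact_rate_intervention",
                      "outreach_contact_rate_control"):
            value = getattr(self, field)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{field} must be in [0, 1], got {value}")
        return self

    @property
    def has_overrides(self) -> bool:
        return (self.per_person_usual_care is not None
                and self.per_person_intervention is not None)

    @property
    def has_denominators(self) -> bool:
        return (self.n_usual_care_denominator is not None
                and self.n_intervention_denominator is not None)


@dataclass(frozen=True)
class CostSummary:
    """Total and per-person costs for one perspective.

    Totals are NaN when per-person overrides were used without
    denominators (the totals are then not identified).
    """

    perspective: str
    per_person_usual_care: float
    per_person_intervention: float
    total_usual_care: float = math.nan
    total_intervention: float = math.nan
    n_usual_care: Optional[int] = None
    n_intervention: Optional[int] = None

    @property
    def incremental_per_person(self) -> float:
        return self.per_person_intervention - self.per_person_usual_care


def ledger_total(
    ledger: Sequence[CostLedgerEntry],
    funder: Optional[str] = None,
    activity: Optional[str] = None,
    arm_scope: Optional[str] = None,
) -> float:
    """Sum of ledger amounts, optionally filtered by funder/activity/scope."""
    return float(sum(
        e.amount_usd for e in ledger
        if (funder is None or e.funder == funder)
        and (activity is None or e.activity == activity)
        and (arm_scope is None or e.arm_scope == arm_scope)
    ))


def allocate_payer_costs(
    ledger: Sequence[CostLedgerEntry], config: CostingConfig
) -> CostSummary:
    """Payer-perspective cost summary from the ledger and config.

    Shared (both-arms) costs are divided evenly over *all* participants;
    intervention-only costs over intervention-arm participants.  So with
    denominators ``n_u`` and ``n_i``::

        per_person_usual_care  = both_arms_total / (n_u + n_i)
        per_person_intervention = per_person_usual_care
                                  + intervention_only_total / n_i

    which conserves money: summing per-person cost times denominator over
    arms returns the full ledger total.  Per-person overrides, when both
    are present, take precedence over allocation.
    """
    if not ledger and not config.has_overrides:
        raise ValueError("allocate_payer_costs requires a nonempty ledger "
                         "or per-person overrides")
    both = ledger_total(ledger, arm_scope="both_arms")
    only_i = ledger_total(ledger, arm_scope="intervention_only")

    if config.has_overrides:
        pp_u = float(config.per_person_usual_care)  # type: ignore[arg-type]
        pp_i = float(config.per_person_intervention)  # type: ignore[arg-type]
    elif config.has_denominators:
        n_u = int(config.n_usual_care_denominator)  # type: ignore[arg-type]
        n_i = int(config.n_intervention_denominator)  # type: ignore[arg-type]
        shared = both / (n_u + n_i)
        pp_u = shared
        pp_i = shared + only_i / n_i
    else:
        raise ValueError(
            "costing config needs either both per-person overrides or both "
            "denominators (n_usual_care_denominator, n_intervention_denominator)"
        )

    total_u = total_i = math.nan
    if config.has_denominators:
        n_u = int(config.n_usual_care_denominator)  # type: ignore[arg-type]
        n_i = int(config.n_intervention_denominator)  # type: ignore[arg-type]
        total_u = pp_u * n_u
        total_i = pp_i * n_i
    return CostSummary(
        perspective="payer",
        per_person_usual_care=pp_u,
        per_person_intervention=pp_i,
        total_usual_care=total_u,
        total_intervention=total_i,
        n_usual_care=config.n_usual_care_denominator,
        n_intervention=config.n_intervention_denominator,
    )


def patient_time_savings(config: CostingConfig, arm: Arm) -> float:
    """Per-person value (US $) of time saved by outreach contact in an arm.

    ``wage x (time_without - time_with) x contacts x arm contact rate``.
    A negative time difference (outreach slower than self-referral) is
    allowed but logged as a warning, since it turns the saving into a cost.
    """
    net_h = config.time_without_outreach_h - config.time_with_outreach_h
    if net_h < 0.0:
        logger.warning(
            "time_without_outreach_h < time_with_outreach_h: negative time "
            "saving of %.3g h per contact", net_h,
        )
    rate = (config.outreach_contact_rate_intervention if arm == "intervention"
            else config.outreach_contact_rate_control)
    return config.hourly_wage_usd * net_h * config.contacts_per_person * rate


def combined_perspective(
    payer: CostSummary, savings_by_arm: Dict[Arm, float]
) -> CostSummary:
    """Payer+patient cost summary: per-person costs net of time savings.

    Each arm's per-person payer cost is reduced by that arm's per-person
    time saving; totals (when identified) are reduced by saving times
    denominator.
    """
    s_u = savings_by_arm.get("control", 0.0)
    s_i = savings_by_arm.get("intervention", 0.0)
    total_u, total_i = payer.total_usual_care, payer.total_intervention
    if payer.n_usual_care is not None and not math.isnan(total_u):
        total_u = total_u - s_u * payer.n_usual_care
    if payer.n_intervention is not None and not math.isnan(total_i):
        total_i = total_i - s_i * payer.n_intervention
    return replace(
        payer,
        perspective="payer_patient",
        per_person_usual_care=payer.per_person_usual_care - s_u,
        per_person_intervention=payer.per_person_intervention - s_i,
        total_usual_care=total_u,
        total_intervention=total_i,
    )
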