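"""Budget impact analysis: undiscounted cost of scaling up the program.

Projects the financial cost of extending the intervention's messaging and
outreach services to a growing share of the target population over a
multi-year horizon.  Enrollment grows by a fixed number of new enrollees
per year; messaging and outreach costs accrue on the *cumulative* covered
population each year (everyone enrolled keeps receiving services), and a
one-off startup (capital) cost lands in year 1 only.  No discounting is
applied anywhere — the projection is a financial budget, not a welfare
calculation — and downstream health-service costs or savings are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["BIAConfig", "BIAResult", "scale_up_schedule", "project_costs",
           "outreach_workforce"]


class BIAConfig(BaseModel):
    """Scale-up schedule parameters and unit costs.

    Defaults describe extending coverage to ~70% of an estimated 50,000
    female entertainment workers over 5 years (6,958 newly enrolled per
    year), with per-person per-year unit costs of US $2.66 for messaging
    and US $9.54 for outreach workers (salaries, training, communication,
    travel at ~280 workers served per outreach worker).  ``startup_cost``
    is applied in year 1 only.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    total_population: int = 50_000
    annual_new_enrollees: int = 6_958
    years: int = 5
    messaging_cost_pp_py: float = 2.66
    outreach_cost_pp_py: float = 9.54
    fews_per_outreach_worker: int = 280
    startup_cost: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "BIAConfig":
        for field in ("total_population", "years", "fews_per_outreach_worker"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        if self.annual_new_enrollees < 0:
            raise ValueError("annual_new_enrollees must be >= 0")
        for field in ("messaging_cost_pp_py", "outreach_cost_pp_py", "startup_cost"):
            if getattr(self, field) < 0.0:
                raise ValueError(f"{field} must be >= 0")
        if self.years * self.annual_new_enrollees > self.total_population:
            raise ValueError(
                "scale-up exceeds the population: years * annual_new_enrollees = "
                f"{self.years * self.annual_new_enrollees} > total_population = "
                f"{self.total_population}"
            )
        return self


@dataclass(frozen=True)
class BIAResult:
    """Per-year budget projection plus horizon summaries.

    ``per_year`` has one row per year with new/cumulative enrollees and
    startup/messaging/outreach/total cost columns.  ``category_shares``
    are fractions of the horizon total and sum to 1.  ``cost_pp_py`` is
    the horizon total divided by the final cumulative coverage: the cost
    per person reached, per year of the horizon (average annual cost per
    person at full scale-up).
    """

    per_year: pd.DataFrame
    horizon_total: float
    category_totals: Dict[str, float]
    category_shares: Dict[str, float]
    final_cumulative: int
    final_coverage_fraction: float
    cost_pp_py: float

    @property
    def average_annual_cost(self) -> float:
        return self.horizon_total / len(self.per_year)


def scale_up_schedule(config: BIAConfig) -> pd.DataFrame:
    """Per-year new enrollees and cumulative coverage.

    Cumulative coverage in year ``y`` (1-based) is
    ``annual_new_enrollees * y``; the config validator guarantees it never
    exceeds the population.
    """
    years = np.arange(1, config.years + 1)
    new = np.full(config.years, config.annual_new_enrollees)
    cumulative = config.annual_new_enrollees * years
    return pd.DataFrame(
        {"year": years, "new_enrollees": new, "cumulative": cumulative}
    )


def project_costs(schedule: pd.DataFrame, config: BIAConfig) -> BIAResult:
    """Project yearly and horizon costs from a scale-up schedule.

    Year-y cost = startup (year 1 only) + cumulative[y] * (messaging +
    outreach per-person per-year rates).  Messaging and outreach accrue on
    cumulative coverage, which is what makes outreach dominate the budget
    as coverage grows.
    """
    table = schedule.copy()
    cumulative = table["cumulative"].to_numpy(dtype=float)
    table["startup_cost"] = 0.0
    if len(table):
        table.loc[table.index[0], "startup_cost"] = config.startup_cost
    table["messaging_cost"] = cumulative * config.messaging_cost_pp_py
    table["outreach_cost"] = cumulative * config.outreach_cost_pp_py
    table["total_cost"] = (
        table["startup_cost"] + table["messaging_cost"] + table["outreach_cost"]
    )

    totals = {
        "startup": float(table["startup_cost"].sum()),
        "messaging": float(table["messaging_cost"].sum()),
        "outreach": float(table["outreach_cost"].sum()),
    }
    horizon = float(table["total_cost"].sum())
    shares = {k: (v / horizon if horizon > 0 else 0.0) for k, v in totals.items()}
    final_cum = int(table["cumulative"].iloc[-1]) if len(table) else 0
    coverage = final_cum / config.total_population
    cost_pp_py = horizon / final_cum if final_cum else math.nan
    return BIAResult(
        per_year=table,
        horizon_total=horizon,
        category_totals=totals,
        category_shares=shares,
        final_cumulative=final_cum,
        final_coverage_fraction=coverage,
        cost_pp_py=cost_pp_py,
    )


def outreach_workforce(schedule: pd.DataFrame, config: BIAConfig) -> np.ndarray:
    """Outreach workers needed per year: ceil(cumulative / caseload).

    Informational only — the cost projection uses the per-person rate, not
    this headcount.
    """
    if config.fews_per_outreach_worker < 1:
        raise ValueError("fews_per_outreach_worker must be >= 1")
    cumulative = schedule["cumulative"].to_numpy(dtype=float)
    return np.ceil(cumulative / config.fews_per_outreach_worker).astype(int)
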