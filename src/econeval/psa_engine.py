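"""Monte Carlo engine for the probabilistic sensitivity analysis.

Parameter uncertainty is propagated by sampling, for each outcome, the two
arms' endline risks from a configurable distribution family (normal in the
base case, beta or uniform as sensitivity analyses) moment-matched to the
reported mean/SD, and the disability weight from a beta distribution
moment-matched to its mean/SD.  Each simulation then evaluates

    dalys_i = (R_intervention_i - R_control_i) / 100 * DW_i

per outcome and sums across outcomes.  Everything is sampled independently
— across outcomes, between arms, and between risks and weights — because
the distributions are fitted separately per arm and outcome and no
correlation structure is specified.

Reproducibility contract
------------------------
One seeded :class:`numpy.random.Generator` drives all draws in a fixed,
outcome-major order: for each outcome in spec order, first the control-arm
risks (``n_sims`` values), then the intervention-arm risks, then the
disability weights.  A degenerate input (SD exactly 0) produces a constant
column and consumes no draws.  At a fixed numpy version the draw matrix is
bit-identical across runs with the same seed and config.

Normal risk draws are deliberately *not* truncated to [0, 100]: truncation
would shift the mean/SD away from the reported moments the family is
matched to.  Out-of-range draws are counted and logged at debug level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .daly_model import OutcomeSpec, RiskSummary

__all__ = [
    "PSAConfig",
    "DrawMatrix",
    "InfeasibleMomentsError",
    "beta_from_moments",
    "uniform_from_moments",
    "sample_draws",
    "predicted_interval",
]

logger = logging.getLogger(__name__)

RISK_FAMILIES = ("normal", "beta", "uniform")


class InfeasibleMomentsError(ValueError):
    """A mean/SD pair that no distribution of the requested family attains."""


class PSAConfig(BaseModel):
    """Simulation settings for the probabilistic analysis.

    ``n_sims`` defaults to 10,000 simulations; ``risk_family`` selects the
    distribution assigned to each arm's endline risk (disability weights
    are always beta).  ``pi_percentiles`` is the percentile pair reported
    as the predicted interval — (5, 95) by convention here, i.e. the
    5th-95th percentile range of the simulated results.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_sims: int = Field(default=10_000, ge=1)
    seed: int = 0
    risk_family: str = "normal"
    pi_percentiles: Tuple[float, float] = (5.0, 95.0)

    @model_validator(mode="after")
    def _check(self) -> "PSAConfig":
        if self.risk_family not in RISK_FAMILIES:
            raise ValueError(
                f"risk_family must be one of {RISK_FAMILIES}, got {self.risk_family!r}"
            )
        lo, hi = self.pi_percentiles
        if not (0.0 < lo < hi < 100.0):
            raise ValueError(
                f"pi_percentiles must be ordered within (0, 100), got {self.pi_percentiles}"
            )
        return self


@dataclass
class DrawMatrix:
    """Per-simulation, per-outcome draws and derived DALY columns.

    All arrays have length ``n_sims``.  Risks are on the percent scale;
    ``dalys`` columns are per person per year.  ``total`` is the row-wise
    sum of the per-outcome DALY columns.
    """

    outcomes: List[str]
    risk_control: Dict[str, np.ndarray]
    risk_intervention: Dict[str, np.ndarray]
    ard: Dict[str, np.ndarray]
    dw: Dict[str, np.ndarray]
    dalys: Dict[str, np.ndarray]
    total: np.ndarray
    config: PSAConfig = field(repr=False)

    @property
    def n_sims(self) -> int:
        return self.total.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame with one column per (outcome, quantity) pair."""
        cols = {}
        for name in self.outcomes:
            cols[f"{name}__risk_control"] = self.risk_control[name]
            cols[f"{name}__risk_intervention"] = self.risk_intervention[name]
            cols[f"{name}__ard"] = self.ard[name]
            cols[f"{name}__dw"] = self.dw[name]
            cols[f"{name}__dalys"] = self.dalys[name]
        cols["total_dalys"] = self.total
        return pd.DataFrame(cols)


def beta_from_moments(mean: float, sd: float) -> Tuple[float, float]:
    """Solve beta shape parameters (alpha, beta) from a mean and SD.

    Uses the method of moments: with ``nu = mean*(1-mean)/sd**2 - 1``,
    ``alpha = mean*nu`` and ``beta = (1-mean)*nu``.  The returned shapes
    reproduce the input moments exactly.

    Raises
    ------
    InfeasibleMomentsError
        If ``sd**2 >= mean*(1-mean)`` (no beta distribution has such a
        large SD at that mean) or the mean lies outside (0, 1).
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must be in (0, 1), got {mean}")
    if sd <= 0.0:
        raise InfeasibleMomentsError(f"beta sd must be > 0, got {sd}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"infeasible beta moments: sd^2 = {var:g} >= mean*(1-mean) = "
            f"{mean * (1.0 - mean):g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def uniform_from_moments(mean: float, sd: float) -> Tuple[float, float]:
    """Bounds ``mean ± sqrt(3)*sd`` of the uniform with those moments."""
    if sd < 0.0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    half_width = np.sqrt(3.0) * sd
    return mean - half_width, mean + half_width


def _draw_risk(
    rng: np.random.Generator,
    summary: RiskSummary,
    family: str,
    n: int,
    explicit_bounds: Optional[Tuple[float, float]],
    outcome: str,
    arm: str,
) -> np.ndarray:
    """Draw one arm's endline risks (percent scale) from the configured family."""
    if summary.sd == 0.0:
        return np.full(n, summary.mean)
    if family == "normal":
        draws = rng.normal(summary.mean, summary.sd, size=n)
        n_out = int(np.count_nonzero((draws < 0.0) | (draws > 100.0)))
        if n_out:
            logger.debug(
                "%d/%d normal risk draws outside [0, 100] for %s/%s (not truncated)",
                n_out, n, outcome, arm,
            )
        return draws
    if family == "beta":
        # moment-match on the proportion scale, then return to percent
        alpha, beta = beta_from_moments(summary.mean / 100.0, summary.sd / 100.0)
        return 100.0 * rng.beta(alpha, beta, size=n)
    if family == "uniform":
        if explicit_bounds is not None:
            low, high = explicit_bounds
        else:
            low, high = uniform_from_moments(summary.mean, summary.sd)
        return rng.uniform(low, high, size=n)
    raise ValueError(f"unknown risk family {family!r}")


def sample_draws(specs: Sequence[OutcomeSpec], config: PSAConfig) -> DrawMatrix:
    """Run the Monte Carlo engine and return the full draw matrix.

    Per simulation and outcome: draw both arms' risks independently from
    ``config.risk_family`` moment-matched to the outcome's summaries, form
    the ARD, draw the disability weight from its moment-matched beta, and
    evaluate ``(ARD/100)*DW``.  The per-simulation total sums the outcome
    columns.

    Raises
    ------
    InfeasibleMomentsError
        If the beta family is requested and any risk, converted to the
        proportion scale, has infeasible beta moments.
    ValueError
        On an empty spec list or duplicate outcome names.
    """
    if not specs:
        raise ValueError("sample_draws requires at least one OutcomeSpec")
    names = [spec.name for spec in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate outcome names in specs: {names}")

    rng = np.random.default_rng(config.seed)
    n = config.n_sims

    risk_c: Dict[str, np.ndarray] = {}
    risk_i: Dict[str, np.ndarray] = {}
    ards: Dict[str, np.ndarray] = {}
    dws: Dict[str, np.ndarray] = {}
    dalys: Dict[str, np.ndarray] = {}
    total = np.zeros(n)

    for spec in specs:
        rc = _draw_risk(
            rng, spec.risk_control, config.risk_family, n,
            spec.risk_control_bounds, spec.name, "control",
        )
        ri = _draw_risk(
            rng, spec.risk_intervention, config.risk_family, n,
            spec.risk_intervention_bounds, spec.name, "intervention",
        )
        if spec.dw.sd == 0.0:
            w = np.full(n, spec.dw.mean)
        else:
            alpha, beta = beta_from_moments(spec.dw.mean, spec.dw.sd)
            w = rng.beta(alpha, beta, size=n)
        a = ri - rc
        d = (a / 100.0) * w

        risk_c[spec.name] = rc
        risk_i[spec.name] = ri
        ards[spec.name] = a
        dws[spec.name] = w
        dalys[spec.name] = d
        total += d

    return DrawMatrix(
        outcomes=names,
        risk_control=risk_c,
        risk_intervention=risk_i,
        ard=ards,
        dw=dws,
        dalys=dalys,
        total=total,
        config=config,
    )


def predicted_interval(
    values: np.ndarray, percentiles: Tuple[float, float] = (5.0, 95.0)
) -> Tuple[float, float]:
    """Empirical predicted interval of a per-simulation column.

    Returns the configured percentile pair (default 5th and 95th) with
    linear interpolation between order statistics.  Requires at least 20
    simulations so the default tail percentiles are anchored by data.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("predicted_interval expects a 1-D column of draws")
    if values.shape[0] < 20:
        raise ValueError(
            f"predicted_interval requires >= 20 simulations, got {values.shape[0]}"
        )
    lo, hi = percentiles
    if not lo < hi:
        raise ValueError(f"percentiles must be ordered, got {percentiles}")
    low, high = np.percentile(values, [lo, hi])
    return float(low), float(high)
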