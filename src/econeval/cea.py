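"""Cost-effectiveness analysis: ICERs, net monetary benefit, and frontiers.

The decision problem compares the intervention against usual care at a
willingness-to-pay threshold λ (US $ per DALY averted).  The headline
statistic is the incremental cost-effectiveness ratio

    ICER = ΔC / E[ΔE]

computed as the ratio of the expected incremental cost to the expected
incremental effect — not the mean of per-simulation ratios, which is
undefined and unstable whenever the simulated effect crosses zero (as it
does here).  The per-simulation ratio distribution remains available from
the draw matrix for inspection.

Decision uncertainty is summarized by the cost-effectiveness acceptability
frontier: at each λ, the probability that each strategy has the higher net
monetary benefit ``NMB = λ·ΔE − ΔC``, with the frontier tracking the
strategy whose *expected* NMB is higher.  Break-even analyses report the
cost reduction or effect multiple needed for the ICER to meet λ.

The default threshold range (US $835–$1671 per DALY averted) corresponds
to 50%–100% of Cambodia's 2019 per-capita GDP, the range conventionally
proposed for that setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .psa_engine import DrawMatrix, predicted_interval

__all__ = [
    "CAMBODIA_THRESHOLDS",
    "DEFAULT_LAMBDA_GRID",
    "ICERResult",
    "CEResult",
    "RequiredEffect",
    "icer",
    "nmb",
    "acceptability_frontier",
    "required_cost_reduction",
    "required_effect",
    "evaluate",
]

#: 50% and 100% of Cambodia's 2019 per-capita GDP, US $/DALY averted.
CAMBODIA_THRESHOLDS: Tuple[float, float] = (835.0, 1671.0)

#: Default willingness-to-pay grid for the acceptability frontier.
DEFAULT_LAMBDA_GRID = np.arange(0.0, 50_000.0 + 250.0, 250.0)

_EFFECT_TOL = 1e-12


@dataclass(frozen=True)
class ICERResult:
    """An ICER with its cost-effectiveness-plane quadrant.

    ``value`` is None (and ``defined`` False) when the mean incremental
    effect is numerically zero.  The quadrant places (ΔE, ΔC) on the CE
    plane: NE = costlier & more effective, NW = costlier & less effective,
    SE = cheaper & more effective, SW = cheaper & less effective.
    """

    value: Optional[float]
    defined: bool
    quadrant: str


@dataclass(frozen=True)
class CEResult:
    """Cost-effectiveness summary for one perspective."""

    perspective: str
    delta_cost_per_person: float
    mean_delta_effect: float
    effect_pi: Tuple[float, float]
    icer: ICERResult
    threshold_range: Tuple[float, float] = CAMBODIA_THRESHOLDS


@dataclass(frozen=True)
class RequiredEffect:
    """Break-even effect at a threshold, with both multiplier conventions.

    ``ratio`` is required/reference; ``ratio_minus_one`` is the "times
    higher" increment.  Both are reported because the two phrasings are
    routinely conflated in the literature; neither is privileged here.
    """

    dalys: float
    ratio: Optional[float] = None
    ratio_minus_one: Optional[float] = None


def icer(delta_cost: float, mean_delta_effect: float) -> ICERResult:
    """ICER as the ratio of expected incremental cost to expected effect."""
    if abs(mean_delta_effect) < _EFFECT_TOL:
        quad = "NE" if delta_cost >= 0 else "SE"
        return ICERResult(value=None, defined=False, quadrant=quad)
    if mean_delta_effect > 0:
        quad = "NE" if delta_cost >= 0 else "SE"
    else:
        quad = "NW" if delta_cost >= 0 else "SW"
    return ICERResult(value=delta_cost / mean_delta_effect, defined=True, quadrant=quad)


def nmb(lam: float, delta_cost: float, delta_effect: float) -> float:
    """Net monetary benefit ``λ·ΔE − ΔC`` of the intervention vs usual care."""
    return lam * delta_effect - delta_cost


def acceptability_frontier(
    draws: DrawMatrix | np.ndarray,
    delta_cost: float,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability frontier over a threshold grid.

    Per λ: ``p_mobile_link_ce`` is the fraction of simulations in which
    the intervention's NMB is positive; probabilities for the two
    strategies sum to one.  The optimal strategy is the one with the
    higher *expected* NMB (usual care on ties), and ``p_optimal`` is the
    optimal strategy's probability — the quantity the frontier plots.

    Accepts either a :class:`DrawMatrix` (its total-DALY column is used)
    or a raw per-simulation ΔE array.
    """
    effect = draws.total if isinstance(draws, DrawMatrix) else np.asarray(draws, float)
    grid = np.asarray(list(lambda_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda_grid must be nonempty")
    if effect.size == 0:
        raise ValueError("acceptability_frontier requires nonempty draws")

    mean_effect = float(effect.mean())
    rows = []
    for lam in grid:
        p_ml = float(np.mean(lam * effect - delta_cost > 0.0))
        expected_nmb = lam * mean_effect - delta_cost
        optimal = "mobile_link" if expected_nmb > 0.0 else "usual_care"
        p_opt = p_ml if optimal == "mobile_link" else 1.0 - p_ml
        rows.append((lam, p_ml, 1.0 - p_ml, optimal, p_opt))
    return pd.DataFrame(
        rows,
        columns=["lambda", "p_mobile_link_ce", "p_usual_care_ce",
                 "optimal_strategy", "p_optimal"],
    )


def required_cost_reduction(
    delta_cost: float, mean_delta_effect: float, lam: float
) -> float:
    """Fractional cost cut needed for the ICER to meet λ, floored at 0.

    ``1 − λ·E[ΔE]/ΔC``; zero when the intervention is already at or below
    the threshold.  Requires a positive mean effect — with no health gain
    no price makes the intervention cost-effective.
    """
    if mean_delta_effect <= 0.0:
        raise ValueError(
            "required_cost_reduction needs mean_delta_effect > 0, "
            f"got {mean_delta_effect}"
        )
    if delta_cost <= 0.0:
        return 0.0
    return max(0.0, 1.0 - (lam * mean_delta_effect) / delta_cost)


def required_effect(
    delta_cost: float, lam: float, reference_effect: Optional[float] = None
) -> RequiredEffect:
    """Break-even DALYs averted ``ΔC/λ`` at threshold λ.

    When ``reference_effect`` is given, the multiplier relative to it is
    reported under both conventions (ratio and ratio − 1).
    """
    if lam <= 0.0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    needed = delta_cost / lam
    if reference_effect is None or reference_effect == 0.0:
        return RequiredEffect(dalys=needed)
    ratio = needed / reference_effect
    return RequiredEffect(dalys=needed, ratio=ratio, ratio_minus_one=ratio - 1.0)


def evaluate(
    draws: DrawMatrix,
    delta_cost: float,
    perspective: str = "payer",
    thresholds: Tuple[float, float] = CAMBODIA_THRESHOLDS,
) -> CEResult:
    """Summarize one perspective's cost-effectiveness from PSA draws."""
    mean_effect = float(draws.total.mean())
    pi = predicted_interval(draws.total, draws.config.pi_percentiles)
    return CEResult(
        perspective=perspective,
        delta_cost_per_person=delta_cost,
        mean_delta_effect=mean_effect,
        effect_pi=pi,
        icer=icer(delta_cost, mean_effect),
        threshold_range=thresholds,
    )
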