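"""Synthetic two-arm trial generator and arm-level risk estimation.

Emulates the statistical structure the downstream model assumes: an
individually randomized two-arm trial with binary endline outcomes,
independent across participants and outcomes, and dropout that is missing
completely at random (outcome-independent).  The generator exists to
exercise the full pipeline end-to-end — estimated arm risks and their
binomial standard errors slot directly into :class:`~econeval.daly_model.OutcomeSpec`
— not to reproduce any real participant data.

``sd_from_ci`` implements the convention used to turn a reported risk and
its upper confidence limit into an SD: ``(upper − mean) / 1.96``, the
exact inverse of ``upper = mean + 1.96·sd``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "TrialSimConfig",
    "ArmRiskEstimate",
    "simulate_trial",
    "estimate_risks",
    "sd_from_ci",
]

ARMS = ("control", "intervention")


class TrialSimConfig(BaseModel):
    """Settings for the synthetic trial.

    ``true_risks`` maps each outcome name to its (control, intervention)
    true endline probabilities.  Dropout applies to each participant
    independently with probability ``dropout_rate``; only retained
    participants enter risk estimation, mirroring a complete-case
    analysis.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_per_arm: int
    true_risks: Mapping[str, Tuple[float, float]]
    dropout_rate: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TrialSimConfig":
        if self.n_per_arm < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1], got {self.dropout_rate}")
        if not self.true_risks:
            raise ValueError("true_risks must name at least one outcome")
        for name, pair in self.true_risks.items():
            for p in pair:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"true risk for {name!r} must be in [0, 1], got {p}"
                    )
        return self


@dataclass(frozen=True)
class ArmRiskEstimate:
    """Estimated endline risk for one arm of one outcome.

    ``risk_mean`` is on the percent scale; ``risk_sd`` is the binomial
    standard error, also in percentage points:
    ``100 * sqrt(p_hat * (1 - p_hat) / n)``.
    """

    outcome: str
    arm: str
    risk_mean: float
    risk_sd: float
    n_used: int


def simulate_trial(config: TrialSimConfig) -> pd.DataFrame:
    """Generate individual-level records for a two-arm trial.

    Returns a frame with ``participant_id``, ``arm``, ``retained`` and one
    binary column per outcome.  Exactly ``n_per_arm`` rows per arm; the
    retained flag and every outcome are drawn independently; the same seed
    reproduces the same records.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_arm
    frames = []
    for arm_index, arm in enumerate(ARMS):
        data = {
            "participant_id": np.arange(arm_index * n, (arm_index + 1) * n),
            "arm": arm,
            "retained": rng.random(n) >= config.dropout_rate,
        }
        for outcome, risks in config.true_risks.items():
            data[outcome] = (rng.random(n) < risks[arm_index]).astype(int)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def estimate_risks(records: pd.DataFrame, outcome: str) -> Dict[str, ArmRiskEstimate]:
    """Per-arm endline risk estimates among retained participants.

    Raises ``ValueError`` if an arm has no retained participants (the risk
    is then unidentified).
    """
    if outcome not in records.columns:
        raise KeyError(f"outcome {outcome!r} not found in records")
    estimates: Dict[str, ArmRiskEstimate] = {}
    for arm in ARMS:
        kept = records[(records["arm"] == arm) & records["retained"]]
        n = len(kept)
        if n == 0:
            raise ValueError(f"no retained participants in arm {arm!r}")
        p_hat = kept[outcome].mean()
        estimates[arm] = ArmRiskEstimate(
            outcome=outcome,
            arm=arm,
            risk_mean=100.0 * p_hat,
            risk_sd=100.0 * float(np.sqrt(p_hat * (1.0 - p_hat) / n)),
            n_used=n,
        )
    return estimates


def sd_from_ci(mean: float, upper_limit: float) -> float:
    """SD from a mean and upper 95% confidence limit: ``(upper − mean)/1.96``."""
    if upper_limit < mean:
        raise ValueError(
            f"upper_limit ({upper_limit}) must be >= mean ({mean})"
        )
    return (upper_limit - mean) / 1.96
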