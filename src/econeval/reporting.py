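"""Assemble result tables with provenance metadata.

Tables carry full float precision internally; any rounding to the
precision conventionally printed (DALYs to 3-4 decimals, dollars to whole
units) happens only at presentation.  Each table's metadata records the
seed, simulation count and distribution family so the producing run can be
repeated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from typing import Dict, Mapping, Optional

import pandas as pd

from . import __version__
from .budget_impact import BIAResult
from .cea import CEResult, RequiredEffect
from .config_io import EvaluationConfig, ResultTable
from .costing import CostSummary
from .psa_engine import DrawMatrix, predicted_interval

__all__ = ["RunManifest", "make_manifest", "table4_analogue", "headline_summary"]


@dataclass(frozen=True)
class RunManifest:
    """Provenance for one pipeline run: enough to reproduce every number."""

    config_hash: str
    seed: int
    n_sims: int
    risk_family: str
    package_version: str
    created: str

    def as_dict(self) -> Dict[str, object]:
        return asdict(self)


def make_manifest(config: EvaluationConfig, seed: int, n_sims: int,
                  risk_family: str) -> RunManifest:
    digest = hashlib.sha256(
        json.dumps(json.loads(config.model_dump_json()), sort_keys=True).encode()
    ).hexdigest()
    return RunManifest(
        config_hash=digest,
        seed=seed,
        n_sims=n_sims,
        risk_family=risk_family,
        package_version=__version__,
        created=datetime.now(timezone.utc).isoformat(),
    )


def table4_analogue(
    draws_by_family: Mapping[str, DrawMatrix],
    manifest: Optional[RunManifest] = None,
) -> ResultTable:
    """Mean DALYs averted and predicted interval per outcome and family.

    One row per (family, outcome) plus a total row per family; columns
    ``mean_dalys``, ``pi_low``, ``pi_high``.  The interval percentiles
    come from each draw matrix's own config.
    """
    if not draws_by_family:
        raise ValueError("table4_analogue requires at least one draw matrix")
    rows = []
    for family, draws in draws_by_family.items():
        pcts = draws.config.pi_percentiles
        for name in draws.outcomes:
            col = draws.dalys[name]
            low, high = predicted_interval(col, pcts)
            rows.append((family, name, float(col.mean()), low, high))
        low, high = predicted_interval(draws.total, pcts)
        rows.append((family, "total", float(draws.total.mean()), low, high))
    data = pd.DataFrame(
        rows, columns=["family", "outcome", "mean_dalys", "pi_low", "pi_high"]
    )
    metadata: Dict[str, object] = {
        "n_sims": {f: d.config.n_sims for f, d in draws_by_family.items()},
        "seed": {f: d.config.seed for f, d in draws_by_family.items()},
        "families": list(draws_by_family),
    }
    if manifest is not None:
        metadata["manifest"] = manifest.as_dict()
    return ResultTable(data=data, metadata=metadata)


def headline_summary(
    cost_summaries: Mapping[str, CostSummary],
    ce_results: Mapping[str, CEResult],
    required_effect: Optional[RequiredEffect] = None,
    required_cost_reduction: Optional[float] = None,
    bia: Optional[BIAResult] = None,
    manifest: Optional[RunManifest] = None,
) -> ResultTable:
    """One table summarizing all three analyses.

    Rows are (metric, value, status); stages that were not run are marked
    ``not_run`` with a null value rather than erroring, so a partial
    pipeline still reports cleanly.
    """
    rows = []

    def add(metric: str, value, status: str = "ok") -> None:
        rows.append((metric, value, status))

    for perspective, summary in cost_summaries.items():
        add(f"incremental_cost_per_person_{perspective}",
            summary.incremental_per_person)
    for perspective, result in ce_results.items():
        add(f"mean_total_dalys_averted_{perspective}", result.mean_delta_effect)
        add(f"dalys_pi_low_{perspective}", result.effect_pi[0])
        add(f"dalys_pi_high_{perspective}", result.effect_pi[1])
        add(f"icer_{perspective}",
            result.icer.value if result.icer.defined else None,
            "ok" if result.icer.defined else "undefined")
    if required_effect is not None:
        add("required_effect_dalys", required_effect.dalys)
        if required_effect.ratio is not None:
            add("required_effect_ratio", required_effect.ratio)
            add("required_effect_times_higher", required_effect.ratio_minus_one)
    if required_cost_reduction is not None:
        add("required_cost_reduction_fraction", required_cost_reduction)
    if bia is not None:
        add("bia_horizon_total", bia.horizon_total)
        add("bia_cost_pp_py", bia.cost_pp_py)
        add("bia_final_coverage_fraction", bia.final_coverage_fraction)
    else:
        for metric in ("bia_horizon_total", "bia_cost_pp_py",
                       "bia_final_coverage_fraction"):
            add(metric, None, "not_run")

    data = pd.DataFrame(rows, columns=["metric", "value", "status"])
    metadata: Dict[str, object] = {}
    if manifest is not None:
        metadata["manifest"] = manifest.as_dict()
    return ResultTable(data=data, metadata=metadata)
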