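"""Config and result-file I/O.

One YAML file drives all three analyses; sections map onto the domain
configs (``outcomes``, ``psa``, ``costing``, ``bia``) and are validated
lazily — a section is only required by the subcommand that uses it.
Unknown keys are rejected, and validation failures enumerate every failing
key path in a single :class:`ConfigError`.

Result tables are written as a CSV plus a JSON metadata sidecar carrying
enough provenance (seed, simulation count, distribution family, ...) to
re-run the producing command bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .budget_impact import BIAConfig
from .costing import CostingConfig, CostLedgerEntry
from .daly_model import OutcomeSpec
from .psa_engine import PSAConfig

__all__ = [
    "ConfigError",
    "EvaluationConfig",
    "ResultTable",
    "load_config",
    "load_default_config",
    "load_cost_ledger",
    "default_ledger_path",
    "write_results",
    "read_results",
]

LEDGER_COLUMNS = ["funder", "activity", "input_type", "amount_usd", "arm_scope"]


class ConfigError(ValueError):
    """A config failed validation; ``keys`` lists every failing key path."""

    def __init__(self, message: str, keys: Optional[List[str]] = None) -> None:
        super().__init__(message)
        self.keys = keys or []


class EvaluationConfig(BaseModel):
    """Top-level config: one artifact drives all three analyses."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    outcomes: Optional[List[OutcomeSpec]] = None
    psa: Optional[PSAConfig] = None
    costing: Optional[CostingConfig] = None
    bia: Optional[BIAConfig] = None
    output_dir: Path = Path("results")
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    def require(self, section: str) -> Any:
        """Return a section, raising :class:`ConfigError` if absent."""
        value = getattr(self, section)
        if value is None:
            raise ConfigError(
                f"config section {section!r} is required by this command "
                "but missing", keys=[section],
            )
        return value


def _format_validation_error(exc: ValidationError) -> ConfigError:
    keys = []
    lines = []
    for err in exc.errors():
        key = ".".join(str(part) for part in err["loc"]) or "<root>"
        keys.append(key)
        lines.append(f"  {key}: {err['msg']}")
    return ConfigError("invalid config:\n" + "\n".join(lines), keys=keys)


def load_config(path: str | Path) -> EvaluationConfig:
    """Load and validate an evaluation config from YAML."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return EvaluationConfig.model_validate(raw)
    except ValidationError as exc:
        raise _format_validation_error(exc) from exc


def _fixture(name: str) -> Path:
    return Path(str(resources.files("econeval").joinpath("fixtures", name)))


def load_default_config() -> EvaluationConfig:
    """The bundled study-condition config (outcomes, PSA, costing, BIA)."""
    return load_config(_fixture("evaluation.yaml"))


def default_ledger_path() -> Path:
    """Path of the bundled payer cost-ledger fixture."""
    return _fixture("table1_ledger.csv")


def load_cost_ledger(path: str | Path) -> List[CostLedgerEntry]:
    """Read a payer cost ledger CSV into validated entries.

    The CSV must carry exactly the header
    ``funder,activity,input_type,amount_usd,arm_scope``; enum values and
    amounts are validated per line.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"ledger file not found: {path}")
    frame = pd.read_csv(path)
    if list(frame.columns) != LEDGER_COLUMNS:
        raise ConfigError(
            f"ledger header must be {','.join(LEDGER_COLUMNS)}, "
            f"got {','.join(map(str, frame.columns))}"
        )
    entries: List[CostLedgerEntry] = []
    for i, row in frame.iterrows():
        try:
            entries.append(CostLedgerEntry(
                funder=row["funder"],
                activity=row["activity"],
                input_type=row["input_type"],
                amount_usd=float(row["amount_usd"]),
                arm_scope=row["arm_scope"],
            ))
        except (ValidationError, ValueError, TypeError) as exc:
            raise ConfigError(f"invalid ledger line {i + 2}: {exc}") from exc
    return entries


@dataclass
class ResultTable:
    """A labelled numeric table plus the metadata needed to reproduce it."""

    data: pd.DataFrame
    metadata: Dict[str, Any] = field(default_factory=dict)


def write_results(table: ResultTable, path: str | Path) -> None:
    """Write a result table as CSV with a ``.meta.json`` sidecar.

    Floats are written with ``repr`` round-trip precision so reading the
    pair back reproduces identical values.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as handle:
        json.dump(table.metadata, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def read_results(path: str | Path) -> ResultTable:
    """Read back a CSV + sidecar pair written by :func:`write_results`."""
    path = Path(path)
    data = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    metadata: Dict[str, Any] = {}
    if sidecar.exists():
        with open(sidecar) as handle:
            metadata = json.load(handle)
    return ResultTable(data=data, metadata=metadata)
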