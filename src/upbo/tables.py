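"""Experiment-table and solvent-table readers/writers, run configuration.

All tabular interchange is plain CSV (comma, UTF-8, ``.`` decimal) in the
campaign's experiment-table schema::

    acoh_equiv, naoh_equiv, menhnh2_equiv, dsi2, ptc, ms, temp_c,
    vol_ml_per_g, solvent, n2_pct, n1_pct, conv_pct[, round_label, strategy]

Percent columns must lie in [0, 100] and the two isomer percentages must sum
to 100 within a +-1 rounding tolerance; violations are reported with the
offending row number.  Solvent names are matched exactly after trimming and
case-folding — silent fuzzy matching would be worse than an error.

The run configuration is a single YAML document validated against a
versioned pydantic schema that rejects unknown keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .acquisition import StrategyLabel
from .objectives import ObjectivePair, UtopiaPoint
from .optimizer import CampaignState, Observation, ProposalBatch
from .space import (
    Condition,
    SearchSpace,
    SolventRecord,
    SpaceError,
    define_space,
    split_acid_base,
)

CONDITION_CSV_COLUMNS = (
    "acoh_equiv",
    "naoh_equiv",
    "menhnh2_equiv",
    "dsi2",
    "ptc",
    "ms",
    "temp_c",
    "vol_ml_per_g",
    "solvent",
)
OUTCOME_COLUMNS = ("n2_pct", "n1_pct", "conv_pct")
OPTIONAL_COLUMNS = ("round_label", "strategy")

ISOMER_SUM_TOL = 1.0


class SchemaError(ValueError):
    """A file does not match the documented schema."""


class RowError(ValueError):
    """A row violates a table invariant; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def read_experiment_table(path) -> pd.DataFrame:
    """Read and validate an experiment table CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected experiment-table header")
    missing = [c for c in CONDITION_CSV_COLUMNS + OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = df.copy()
    df["solvent"] = df["solvent"].astype(str).str.strip()
    for i, row in df.iterrows():
        rowno = int(i) + 1
        for col in ("dsi2", "ptc", "ms"):
            if row[col] not in (0, 1):
                raise RowError(rowno, f"{col} must be 0/1, got {row[col]!r}")
        for col in OUTCOME_COLUMNS:
            v = float(row[col])
            if not 0.0 <= v <= 100.0:
                raise RowError(rowno, f"{col} out of [0, 100]: {v}")
        if abs(float(row["n1_pct"]) + float(row["n2_pct"]) - 100.0) > ISOMER_SUM_TOL:
            raise RowError(
                rowno,
                f"n1_pct + n2_pct must equal 100 +- {ISOMER_SUM_TOL}, "
                f"got {row['n1_pct']} + {row['n2_pct']}",
            )
        if float(row["acoh_equiv"]) > 0 and float(row["naoh_equiv"]) > 0:
            raise RowError(rowno, "row uses both acid and base")
    return df


def write_experiment_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in CONDITION_CSV_COLUMNS + OUTCOME_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def read_solvent_table(path) -> dict[str, SolventRecord]:
    """Solvent descriptor CSV (header ``solvent,d1,d2,d3,d4``) -> records."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty solvent table")
    needed = ["solvent", "d1", "d2", "d3", "d4"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: solvent table missing column(s) {missing}")
    return {
        str(r["solvent"]).strip(): SolventRecord(
            str(r["solvent"]).strip(), (r["d1"], r["d2"], r["d3"], r["d4"])
        )
        for _, r in df.iterrows()
    }


def write_solvent_table(records: dict[str, SolventRecord], path) -> None:
    pd.DataFrame(
        {
            "solvent": [r.name for r in records.values()],
            **{
                f"d{i + 1}": [r.descriptors[i] for r in records.values()]
                for i in range(4)
            },
        }
    ).to_csv(path, index=False)


def condition_to_row(cond: Condition) -> dict:
    """Condition -> experiment-table condition columns (acid/base split back)."""
    acid, base = split_acid_base(cond["acid_base_equiv"])
    return {
        "acoh_equiv": acid,
        "naoh_equiv": base,
        "menhnh2_equiv": cond["menhnh2_equiv"],
        "dsi2": int(cond["dsi2"]),
        "ptc": int(cond["ptc"]),
        "ms": int(cond["ms"]),
        "temp_c": cond["temp_c"],
        "vol_ml_per_g": cond["vol_ml_per_g"],
        "solvent": cond["solvent"],
    }


def write_proposals(batch: ProposalBatch, path) -> None:
    """Proposed batch -> CSV in experiment-table column order plus strategy
    and acquisition score; re-readable once outcome columns are appended."""
    rows = []
    for p in batch.proposals:
        row = condition_to_row(p.condition)
        row["strategy"] = p.label
        row["acquisition_score"] = p.score
        rows.append(row)
    cols = list(CONDITION_CSV_COLUMNS) + ["strategy", "acquisition_score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


class VariableConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    kind: str
    levels: list | None = None
    min: float | None = None
    max: float | None = None
    step: float | None = None
    unit: str | None = None


class SpaceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    solvent_table: str
    variables: list[VariableConfig]


class UtopiaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sel: float = 110.0
    conv: float = 110.0
    w_sel: float = 1.0
    w_conv: float = 1.0

    def build(self) -> UtopiaPoint:
        return UtopiaPoint(self.sel, self.conv, self.w_sel, self.w_conv)


class BenchmarkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    repeats: int = 20
    max_rounds: int = 15
    n_seed_points: int = 5


class RunConfig(BaseModel):
    """Versioned campaign configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = 1
    mode: str = "upbo"
    isomer: str = "n2"
    batch_size: int = Field(default=8, ge=1)
    pool_size: int = Field(default=50_000, ge=1)
    seed: int = 0
    utopia: dict[str, UtopiaConfig] = Field(
        default_factory=lambda: {"n1": UtopiaConfig(), "n2": UtopiaConfig()}
    )
    strategies: list[str] = Field(
        default_factory=lambda: [
            "GPR_ei_05_n2", "GPR_ucb_2_n2", "RFR_ei_05_n2", "RFR_ucb_2_n2",
            "Grad_ei_05_n2", "Grad_ucb_2_n2", "MLP_ei_05_n2", "MLP_ucb_2_n2",
        ]
    )
    space: SpaceConfig | None = None
    benchmark: BenchmarkConfig = Field(default_factory=BenchmarkConfig)

    def strategy_labels(self) -> list[StrategyLabel]:
        return [StrategyLabel.parse(s) for s in self.strategies]

    def utopia_point(self) -> UtopiaPoint:
        return self.utopia[self.isomer].build()


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return RunConfig(**data)


def build_space_from_config(cfg: RunConfig, base_dir: Path | None = None) -> SearchSpace:
    if cfg.space is None:
        raise SpaceError("configuration has no space block")
    base = base_dir or Path(".")
    records = read_solvent_table(base / cfg.space.solvent_table)
    config = {"variables": [v.model_dump(exclude_none=True) for v in cfg.space.variables]}
    return define_space(config, records)


# ---------------------------------------------------------------------------
# state serialization (single JSON document)


def _space_to_doc(space: SearchSpace) -> dict:
    return {
        "variables": [
            {"name": v.name, "kind": v.kind, "levels": list(v.levels), "unit": v.unit}
            for v in space.variables
        ],
        "solvent_table": {r.name: list(r.descriptors) for r in space.solvent_table.values()},
    }


def _space_from_doc(doc: dict) -> SearchSpace:
    from .space import VariableSpec

    variables = tuple(
        VariableSpec(v["name"], v["kind"], tuple(v["levels"]), v.get("unit"))
        for v in doc["variables"]
    )
    records = {k: SolventRecord(k, tuple(d)) for k, d in doc["solvent_table"].items()}
    return SearchSpace(variables, records)


def save_state(state: CampaignState, path) -> None:
    doc = {
        "schema_version": 1,
        "space": _space_to_doc(state.space),
        "utopia": {
            "sel": state.utopia.selectivity,
            "conv": state.utopia.conversion,
            "w_sel": state.utopia.w_sel,
            "w_conv": state.utopia.w_conv,
        },
        "strategies": [s.render() for s in state.strategies],
        "mode": state.mode,
        "round": state.round,
        "rng_seed": state.rng_seed,
        "events": list(state.events),
        "observations": [
            {
                "condition": o.condition.as_dict(),
                "conversion": o.objectives.conversion,
                "selectivity": o.objectives.selectivity,
                "round": o.round_index,
                "label": o.label,
            }
            for o in state.observations
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_state(path) -> CampaignState:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    space = _space_from_doc(doc["space"])
    u = doc["utopia"]
    observations = tuple(
        Observation(
            Condition.from_dict(o["condition"]),
            ObjectivePair(conversion=o["conversion"], selectivity=o["selectivity"]),
            round_index=o["round"],
            label=o["label"],
        )
        for o in doc["observations"]
    )
    return CampaignState(
        space=space,
        utopia=UtopiaPoint(u["sel"], u["conv"], u["w_sel"], u["w_conv"]),
        strategies=tuple(StrategyLabel.parse(s) for s in doc["strategies"]),
        observations=observations,
        round=doc["round"],
        mode=doc["mode"],
        rng_seed=doc["rng_seed"],
        events=tuple(doc.get("events", ())),
    )
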