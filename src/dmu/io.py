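"""CSV/JSON/YAML input-output and schema validation.

CSV is the sole tabular format; missing predictor cells are written as empty
fields and read back from a configurable set of sentinels.  The outcome
column must be fully observed — a table with a missing outcome is rejected
at read time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import TabularDataset
from .simulate import ScenarioConfig

__all__ = ["read_table", "write_table", "load_scenario_config", "DEFAULT_MISSING_CODES"]

DEFAULT_MISSING_CODES = ("", "NA", "NaN", "nan")


def read_table(
    path,
    outcome: str = "y",
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES,
) -> TabularDataset:
    """Read a CSV table into a :class:`TabularDataset`.

    Raises with the offending row/column on non-numeric cells and rejects
    tables whose outcome column contains missing values.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        na_values=list(missing_codes),
        keep_default_na=False,
        dtype=str,
        skipinitialspace=True,
    )
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not found in {path.name}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric cell at row {row + 2}, column {col!r}: {df[col][row]!r}"
            )
        numeric[col] = converted
    if numeric[outcome].isna().any():
        row = int(numeric[outcome].isna().idxmax())
        raise ValueError(
            f"missing outcome value at row {row + 2}: the outcome column must "
            "be fully observed"
        )
    predictors = numeric.drop(columns=[outcome])
    return TabularDataset(
        outcome=numeric[outcome].to_numpy(float),
        predictors=predictors.to_numpy(float),
        column_names=list(predictors.columns),
        outcome_name=outcome,
    )


def write_table(data: TabularDataset, path) -> None:
    """Write a table to CSV; missing cells become empty fields."""
    df = pd.DataFrame(data.predictors, columns=data.column_names)
    df.insert(0, data.outcome_name, data.outcome)
    df.to_csv(path, index=False, na_rep="")


def load_scenario_config(path) -> ScenarioConfig:
    """Load a scenario config from YAML or JSON, rejecting unknown keys."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path.name} must be a mapping")
    allowed = set(ScenarioConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "beta" in raw and raw["beta"] is not None:
        raw["beta"] = np.asarray(raw["beta"], dtype=float)
    if "corr_range" in raw:
        raw["corr_range"] = tuple(raw["corr_range"])
    return ScenarioConfig(**raw)
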