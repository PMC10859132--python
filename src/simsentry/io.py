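"""CSV and JSON round-tripping for the study's data sets.

All tabular artifacts are RFC-4180 CSV, UTF-8, '.' decimal, with an empty
field for a missing value and full double precision via shortest
round-trip formatting. A caution for externally supplied estimates files:
the ``se`` column must contain standard error estimates, not variances —
the reader cannot tell them apart (values that look like squared SEs are a
classic authoring mistake) and performs no auto-detection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ESTIMATE_COLUMNS, STATE_COLUMNS

__all__ = [
    "write_estimates", "read_estimates",
    "write_states", "read_states",
    "write_dataset", "read_dataset",
    "write_performance", "read_performance",
    "write_zip_data", "write_metadata",
    "SchemaError",
]

DATASET_COLUMNS = ["rep_id", "dgm", "C", "E", "D", "M_C"]
PERFORMANCE_COLUMNS = ["dgm", "method", "measure", "estimate", "mcse", "n_used", "n_failed"]
ZIP_COLUMNS = ["dgm", "method", "rep_id", "rank_fraction", "p_value", "ci_low", "ci_high", "covers"]


class SchemaError(ValueError):
    """A CSV whose header does not match the documented schema."""


def _check_schema(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{what} CSV schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}; expected exactly {expected}"
        )


def _write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # shortest round-trip float formatting (repr of Python floats)
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def write_estimates(estimates: pd.DataFrame, path) -> None:
    _check_schema(estimates, ESTIMATE_COLUMNS, "estimates")
    _write_csv(estimates, path)


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_schema(df, ESTIMATE_COLUMNS, "estimates")
    df["rep_id"] = df["rep_id"].astype(np.int64)
    for col in ("separation", "backup_used"):
        df[col] = df[col].astype(np.int64)
    for col in ("estimate", "se", "ci_low", "ci_high", "df"):
        df[col] = df[col].astype(float)
    return df


def write_states(states: pd.DataFrame, path) -> None:
    _check_schema(states, STATE_COLUMNS, "states")
    _write_csv(states, path)


def read_states(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype={"state_token": str, "analysis_state_token": str})
    _check_schema(df, STATE_COLUMNS, "states")
    df["rep_id"] = df["rep_id"].astype(np.int64)
    return df


def write_dataset(data, path, masked: bool = False) -> None:
    """One simulated data set as CSV; ``masked=True`` writes the analyst's
    view with an empty C field wherever M_C = 1."""
    df = data.observed_view() if masked else data.df.copy()
    df.insert(0, "dgm", data.dgm_label)
    df.insert(0, "rep_id", data.rep_id)
    _write_csv(df[DATASET_COLUMNS], path)


def read_dataset(path):
    from .dgm import SimulatedDataset

    df = pd.read_csv(path, float_precision="round_trip")
    _check_schema(df, DATASET_COLUMNS, "dataset")
    rep_id = int(df["rep_id"].iloc[0])
    dgm = str(df["dgm"].iloc[0])
    return SimulatedDataset(
        rep_id=rep_id, dgm_label=dgm, df=df[["C", "E", "D", "M_C"]].reset_index(drop=True)
    )


def write_performance(table: pd.DataFrame, path) -> None:
    _check_schema(table, PERFORMANCE_COLUMNS, "performance")
    _write_csv(table, path)


def read_performance(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_schema(df, PERFORMANCE_COLUMNS, "performance")
    return df


def write_zip_data(zip_tables: dict, path) -> None:
    """Concatenate per-cell zip tables into one CSV keyed by dgm and method."""
    frames = []
    for (dgm, method), tbl in zip_tables.items():
        t = tbl.copy()
        t.insert(0, "method", method)
        t.insert(0, "dgm", dgm)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out["covers"] = out["covers"].astype(int)
    _write_csv(out[ZIP_COLUMNS], path)


def write_metadata(path, *, seed: int, plan_echo: dict, version: str, timestamp: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"seed": seed, "plan": plan_echo, "package_version": version, "timestamp": timestamp},
            fh,
            indent=2,
        )
        fh.write("\n")
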