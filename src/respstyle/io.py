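"""CSV / JSON input and output for all pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .model import MISSING, ItemParameters, ModelSpec, ResponseMatrix


def read_responses(path: str | Path, n_categories: int = 5) -> ResponseMatrix:
    """Read a persons x items response CSV.

    Expects a ``person_id`` column plus one integer column per item.
    Blank cells become missing responses; the person is retained.
    Out-of-range categories and duplicated person ids are hard errors
    naming the offending cell or id.
    """
    df = pd.read_csv(path)
    if "person_id" not in df.columns:
        raise DataError(f"{path}: no person_id column")
    if df["person_id"].duplicated().any():
        dup = df["person_id"][df["person_id"].duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate person_id {dup!r}")
    item_cols = [c for c in df.columns if c != "person_id"]
    if not item_cols:
        raise DataError(f"{path}: no item columns")
    vals = df[item_cols].to_numpy(dtype=float)
    resp = np.where(np.isnan(vals), MISSING, vals)
    if np.any(resp[~np.isnan(vals)] != np.round(resp[~np.isnan(vals)])):
        raise DataError(f"{path}: non-integer response values")
    resp = resp.astype(int)
    observed = resp != MISSING
    bad = observed & ((resp < 1) | (resp > n_categories))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"{path}: response {resp[i, j]} outside 1..{n_categories} at "
            f"person_id {df['person_id'].iloc[i]!r}, column {item_cols[j]!r}"
        )
    return ResponseMatrix(responses=resp, person_ids=tuple(df["person_id"]))


def write_responses(data: ResponseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        np.where(data.responses == MISSING, np.nan, data.responses),
        columns=[f"item{j + 1}" for j in range(data.n_items)],
    )
    df.insert(0, "person_id", list(data.person_ids))
    df.to_csv(path, index=False, float_format="%g")


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"person_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if not df["event"].isin([0, 1, 2]).all():
        raise DataError(f"{path}: event codes must be 0 (censored), 1 or 2")
    if (df["time"] < 0).any():
        raise DataError(f"{path}: negative follow-up times")
    return df


def write_item_parameters(params: ItemParameters, spec: ModelSpec,
                          path: str | Path) -> None:
    """Long-format CSV: item, category, intercept, slope per dimension."""
    params.to_frame(spec).to_csv(path, index=False, float_format="%.10g")


def read_item_parameters(path: str | Path, spec: ModelSpec) -> ItemParameters:
    df = pd.read_csv(path)
    J, K = spec.n_items, spec.n_categories
    if len(df) != J * K:
        raise DataError(f"{path}: expected {J * K} rows, found {len(df)}")
    df = df.sort_values(["item", "category"])
    intercepts = df["intercept"].to_numpy(dtype=float).reshape(J, K)
    slopes = np.stack(
        [df[f"slope_{lab}"].to_numpy(dtype=float).reshape(J, K)
         for lab in spec.dim_labels],
        axis=2,
    )
    params = ItemParameters(slopes=slopes, intercepts=intercepts)
    params.validate_against(spec)
    return params


def write_fitted_model(fit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_json_dict(), fh, indent=1)
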