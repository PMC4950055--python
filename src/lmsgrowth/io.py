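"""Readers and writers for the three plain-text formats.

* Records CSV: header ``sex,gest_weeks,weight_g,year,outcome,karyotype``;
  missing values are empty fields; columns matched by name, extra order is
  accepted.
* LMS table TSV: header ``week<TAB>sex<TAB>L<TAB>M<TAB>S``, sex in {M, F},
  one row per (week, sex), gap-free per sex.
* Centile table TSV: one file per sex, one row per week, columns are the
  centile labels, integer grams.

All writers are deterministic: rows sorted week-ascending, M before F.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bccg import CentileSpec, CentileTable, LMSTable
from .model import FitConfig
from .simulate import RECORD_COLUMNS, OUTCOMES, KARYOTYPES, SimulationConfig

__all__ = [
    "SchemaError",
    "read_records",
    "write_records",
    "read_lms_table",
    "write_lms_table",
    "read_centile_table",
    "write_centile_table",
    "load_config",
]


class SchemaError(ValueError):
    """A file does not match its declared schema (bad header, value, or gap)."""


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a records CSV, validating codes and value ranges row by row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sex": str, "outcome": str, "karyotype": str})
    except OSError as err:
        raise OSError(f"cannot read records file {path}: {err}") from err
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = df.reindex(columns=RECORD_COLUMNS)

    def _bad_rows(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = (df.index[mask] + 2).tolist()[:5]  # 1-based incl. header
            raise SchemaError(f"{path}: {what} at file row(s) {rows}")

    _bad_rows(~df["sex"].isin(["M", "F"]), "sex must be M or F")
    _bad_rows(~df["outcome"].isin(OUTCOMES), f"outcome must be one of {OUTCOMES}")
    _bad_rows(~df["karyotype"].isin(KARYOTYPES), f"karyotype must be one of {KARYOTYPES}")
    weight = pd.to_numeric(df["weight_g"], errors="coerce")
    _bad_rows(df["weight_g"].notna() & weight.isna(), "weight_g must be numeric")
    _bad_rows(weight.notna() & (weight <= 0), "weight_g must be positive")
    gest = pd.to_numeric(df["gest_weeks"], errors="coerce")
    _bad_rows(df["gest_weeks"].notna() & gest.isna(), "gest_weeks must be integer")
    _bad_rows(gest.notna() & (gest != gest.round()), "gest_weeks must be whole weeks")
    _bad_rows(df["year"].isna() | (pd.to_numeric(df["year"], errors="coerce").isna()), "year must be integer")

    df["weight_g"] = weight
    df["gest_weeks"] = gest.round().astype("Int64")
    df["year"] = df["year"].astype(int)
    return df


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write records CSV; missing values become empty fields."""
    out = records.reindex(columns=RECORD_COLUMNS).copy()
    out.to_csv(path, index=False, na_rep="")


def read_lms_table(path: str | Path) -> LMSTable:
    """Read an LMS TSV; gap and parameter validation happens in LMSTable."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    expected = ["week", "sex", "L", "M", "S"]
    if list(df.columns) != expected:
        raise SchemaError(f"{path}: header must be {expected}, got {list(df.columns)}")
    try:
        return LMSTable(df)
    except ValueError as err:
        raise SchemaError(f"{path}: {err}") from err


def write_lms_table(table: LMSTable, path: str | Path) -> None:
    df = table.to_frame().reindex(columns=["week", "sex", "L", "M", "S"])
    df.to_csv(path, sep="\t", index=False)


def write_centile_table(centiles: CentileTable, sex: str, path: str | Path) -> None:
    frame = centiles.frame(sex).copy()
    frame.insert(0, "week", frame.index)
    frame.to_csv(path, sep="\t", index=False)


def read_centile_table(path: str | Path, sex: str) -> CentileTable:
    df = pd.read_csv(Path(path), sep="\t")
    if df.columns[0] != "week":
        raise SchemaError(f"{path}: first column must be 'week'")
    labels = list(df.columns[1:])
    frame = df.set_index("week")[labels].astype(int)
    return CentileTable({sex: frame}, labels)


def load_config(path: str | Path) -> dict:
    """Load a flat key-value config file into FitConfig/SimulationConfig kwargs.

    Keys must match field names of the two config dataclasses; two-element
    lists become tuples (week/year ranges).  Returns
    ``{"fit": FitConfig, "sim_overrides": dict}`` where simulation overrides
    are applied on top of :class:`SimulationConfig` defaults by the caller.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected flat key-value pairs")
    fit_fields = set(FitConfig.__dataclass_fields__)
    sim_fields = set(SimulationConfig.__dataclass_fields__) - {"count_table", "lms_table"}
    fit_kwargs, sim_kwargs = {}, {}
    for key, value in raw.items():
        if isinstance(value, list) and len(value) == 2:
            value = tuple(value)
        if key in fit_fields:
            fit_kwargs[key] = value
        elif key in sim_fields:
            sim_kwargs[key] = value
        else:
            raise SchemaError(f"{path}: unknown config key {key!r}")
    return {"fit": FitConfig(**fit_kwargs), "sim_overrides": sim_kwargs}
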