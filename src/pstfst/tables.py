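"""Delimited-table glue: posterior draw tables and their sidecar configs.

Draw tables are TSV on write (delimiter auto-detected on read): a header row
of parameter names, one row per retained MCMC draw.  A sidecar JSON config
maps columns to (parameter, population) and, for migration columns, names the
paired theta column so Nm can be formed iteration-by-iteration.
"""

from __future__ import annotations

import json
from typing import Mapping

import pandas as pd

from .im_convert import PosteriorDraws

__all__ = [
    "read_draws_table",
    "write_draws_tsv",
    "read_column_config",
    "draws_from_table",
]


def read_draws_table(path) -> pd.DataFrame:
    """Read a draw table, auto-detecting tab/comma/whitespace delimiters."""
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        sep = "\t"
    elif "," in header:
        sep = ","
    else:
        sep = r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        raise ValueError(f"{path}: no draws")
    return df


def write_draws_tsv(path, columns: Mapping[str, "list | object"]) -> None:
    pd.DataFrame(dict(columns)).to_csv(path, sep="\t", index=False)


def read_column_config(path) -> dict:
    """Sidecar JSON: {"columns": {col: {"parameter": ..., "population": ...,
    "theta_column": ...}}}."""
    with open(path) as fh:
        cfg = json.load(fh)
    if "columns" not in cfg or not isinstance(cfg["columns"], dict):
        raise ValueError(f"{path}: sidecar config needs a 'columns' mapping")
    return cfg


def draws_from_table(df: pd.DataFrame, column: str, parameter: str,
                     population: str = "NA", units: str = "") -> PosteriorDraws:
    if column not in df.columns:
        raise ValueError(f"column {column!r} not in table "
                         f"(available: {list(df.columns)})")
    return PosteriorDraws(
        parameter=parameter,
        draws=df[column].to_numpy(dtype=float),
        population=population,
        units=units,
    )
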