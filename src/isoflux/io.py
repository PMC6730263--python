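"""Delimited-text readers and writers for the pipeline tables.

All tables are comma-separated UTF-8 with ISO-8601 timestamps and "."
decimals; floats are written with fixed six-decimal formatting so that a
given seed produces bit-identical files across platforms.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.6f"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, date_format="%Y-%m-%dT%H:%M:%S")
    return path


def _read(path, timestamp_cols=("timestamp",), date_cols=()):
    df = pd.read_csv(path)
    for col in timestamp_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    for col in date_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.date
    return df


def read_meteo(path) -> pd.DataFrame:
    return _read(path)


def read_chamber(path) -> pd.DataFrame:
    df = _read(path)
    df["dark"] = df["dark"].astype(bool)
    return df


def read_isotopes(path) -> pd.DataFrame:
    return _read(path)


def read_ec(path) -> pd.DataFrame:
    return _read(path)


def read_fluxes(path) -> pd.DataFrame:
    df = _read(path)
    if "dark" in df.columns:
        df["dark"] = df["dark"].astype(bool)
    return df


def read_daily(path) -> pd.DataFrame:
    return _read(path, timestamp_cols=("sunrise", "sunset"), date_cols=("date",))
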