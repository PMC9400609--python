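"""Delimited-text round-trip for trial tables.

One row per presented trial: participant, block, trial_in_block,
trial_type, foreperiod_ms, rt_ms, accuracy, iti_ms.  Catch trials carry no
foreperiod, RT or accuracy; those fields are written as empty cells.
UTF-8, header row required.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TRIAL_COLUMNS


class TrialTableError(ValueError):
    """Malformed trial table; the message names the offending file line."""


def write_trials(path: str | Path, table: pd.DataFrame) -> None:
    """Write a trial table as CSV (catch-trial fields left empty)."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"trial table missing columns: {missing}")
    table[list(TRIAL_COLUMNS)].to_csv(path, index=False, encoding="utf-8")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises :class:`TrialTableError` naming the first malformed line
    (1-based, header = line 1) when a catch row carries RT/foreperiod/
    accuracy data or a regular row lacks them.
    """
    table = pd.read_csv(
        path,
        dtype={"participant": np.int64, "block": np.int64,
               "trial_in_block": np.int64, "trial_type": str,
               "foreperiod_ms": float, "rt_ms": float, "iti_ms": float},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    table = table[list(TRIAL_COLUMNS)]
    table["accuracy"] = table["accuracy"].astype(object).where(
        table["accuracy"].notna(), ""
    )
    bad_type = ~table["trial_type"].isin(["regular", "catch"])
    is_catch = table["trial_type"] == "catch"
    catch_with_data = is_catch & (
        table["foreperiod_ms"].notna() | table["rt_ms"].notna()
        | (table["accuracy"] != "")
    )
    regular_missing = ~is_catch & ~bad_type & (
        table["foreperiod_ms"].isna() | table["rt_ms"].isna()
        | ~table["accuracy"].isin(["correct", "error"])
    )
    for mask, what in (
        (bad_type, "trial_type must be 'regular' or 'catch'"),
        (catch_with_data, "catch trial must not carry foreperiod/RT/accuracy"),
        (regular_missing, "regular trial must carry foreperiod, RT and accuracy"),
    ):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise TrialTableError(f"{path}: line {row + 2}: {what}")
    return table
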