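"""Trial annotation, exclusion rules and model-input construction.

Annotation attaches previous-trial context (the immediately preceding
presented trial within the same block, catch trials included), the time
indices t (previous presented trials within the block) and b (previous
blocks), and the covariate coding of :mod:`fpseq.models`.

Exclusions follow the published rules: regular trials with RT below 100 ms
or above 1000 ms (strict bounds; 100 and 1000 exactly are retained), the
first trial of each block, and trials following an incorrect response or a
catch trial.  In designs without catch trials the catch rules are inert.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Attribution order for the exclusion report (first matching rule wins).
EXCLUSION_RULES = ("rt_low", "rt_high", "first_of_block", "post_error", "post_catch")


@dataclass(frozen=True)
class ExclusionReport:
    """Counts of excluded regular (non-catch) trials, per first-matching rule."""

    n_regular_presented: int
    n_excluded_regular: int
    per_rule: dict[str, int]

    @property
    def proportion_excluded(self) -> float:
        return self.n_excluded_regular / self.n_regular_presented

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self) | {"proportion_excluded": self.proportion_excluded}
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def annotate(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach previous-trial context, time indices and model covariates.

    Practice blocks (block < 0) are dropped before annotation; b indexes
    test blocks from 0.  Covariates are NaN when the previous trial is
    missing or was a catch trial (those rows are removed by the exclusion
    rules before modelling).
    """
    required = ["participant", "block", "trial_in_block"]
    trials = trials[trials["block"] >= 0].reset_index(drop=True)
    keys = trials[required]
    if keys.duplicated().any():
        raise ValueError("duplicated (participant, block, trial_in_block) keys")
    if not keys.equals(keys.sort_values(required, ignore_index=True)):
        raise ValueError("trials must be sorted by participant, block, trial_in_block")

    out = trials.copy()
    grp = out.groupby(["participant", "block"], sort=False)
    out["prev_foreperiod"] = grp["foreperiod_ms"].shift(1)
    out["prev_type"] = grp["trial_type"].shift(1).fillna("none")
    out["prev_accuracy"] = grp["accuracy"].shift(1).fillna("none")
    out.loc[out["prev_accuracy"] == "", "prev_accuracy"] = "none"
    out["t"] = out["trial_in_block"]
    out["b"] = out["block"]

    fp, pfp = out["foreperiod_ms"], out["prev_foreperiod"]
    long_fp = fp.max()  # two-foreperiod designs: the larger value is "long"
    usable = fp.notna() & pfp.notna()
    out["x_cf"] = np.where(fp.notna() & (fp == long_fp), 1.0, 0.0)
    out.loc[fp.isna(), "x_cf"] = np.nan
    out["x_fs"] = np.where(usable, (fp != pfp).astype(float), np.nan)
    out["x_in"] = np.where(usable, -(pfp == long_fp).astype(float), np.nan)
    return out


def apply_exclusions(
    trials: pd.DataFrame,
    rt_low: float = 100.0,
    rt_high: float = 1000.0,
    has_catch: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the outlier and context exclusion rules to an annotated table.

    Returns the retained trials and a report whose per-rule counts cover
    regular trials only and attribute each excluded trial to its first
    matching rule.  ``has_catch=False`` disables the catch-related rules.
    """
    regular = trials["trial_type"] == "regular"
    rt = trials["rt_ms"]
    rules: dict[str, pd.Series] = {
        "rt_low": regular & (rt < rt_low),
        "rt_high": regular & (rt > rt_high),
        "first_of_block": regular & (trials["trial_in_block"] == 0),
        "post_error": regular & (trials["prev_accuracy"] == "error"),
        "post_catch": regular & (trials["prev_type"] == "catch")
        if has_catch else regular & False,
    }
    excluded = pd.Series(False, index=trials.index)
    per_rule: dict[str, int] = {}
    for name in EXCLUSION_RULES:
        hit = rules[name] & ~excluded
        per_rule[name] = int(hit.sum())
        excluded |= rules[name]
    retained = trials[regular & ~excluded].reset_index(drop=True)
    report = ExclusionReport(
        n_regular_presented=int(regular.sum()),
        n_excluded_regular=int((regular & excluded).sum()),
        per_rule=per_rule,
    )
    if len(retained) == 0:
        log.warning("exclusion rules removed every trial")
    return retained, report


#: Column order of the model input matrix.
DESIGN_COLUMNS = (
    "participant", "rt", "x_cf", "x_fs", "x_in", "t", "b",
    "cf_t", "cf_b", "fs_t", "fs_b", "in_t", "in_b",
)


def build_design_rows(retained: pd.DataFrame) -> pd.DataFrame:
    """Model input matrix from retained trials.

    Columns (stable order): participant, rt, the three cell covariates,
    the baseline drift regressors t and b, and the six covariate-by-time
    interactions (x_cf*t, x_cf*b, ..., x_in*b).
    """
    if len(retained) == 0:
        return pd.DataFrame(columns=list(DESIGN_COLUMNS))
    cov = retained[["x_cf", "x_fs", "x_in"]]
    if cov.isna().any().any():
        bad = int(cov.isna().any(axis=1).idxmax())
        raise ValueError(
            f"undefined covariates at row {bad}; run apply_exclusions first"
        )
    out = pd.DataFrame({
        "participant": retained["participant"],
        "rt": retained["rt_ms"].astype(float),
        "x_cf": retained["x_cf"].astype(float),
        "x_fs": retained["x_fs"].astype(float),
        "x_in": retained["x_in"].astype(float),
        "t": retained["t"].astype(float),
        "b": retained["b"].astype(float),
    })
    for short, col in (("cf", "x_cf"), ("fs", "x_fs"), ("in", "x_in")):
        out[f"{short}_t"] = out[col] * out["t"]
        out[f"{short}_b"] = out[col] * out["b"]
    return out[list(DESIGN_COLUMNS)].reset_index(drop=True)
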