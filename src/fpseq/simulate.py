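"""Synthetic variable-foreperiod experiments.

The generator is the exact generative twin of the fitted model: trial-mean
RT is the additive four-family structure of :mod:`fpseq.models` with linear
trial- and block-level drift, participant-varying baseline intercepts,
Gaussian residual noise on the millisecond scale, Bernoulli response errors,
and an optional outlier mixture (fast anticipations below the lower RT
bound, slow lapses above the upper one) emulating the contaminated tails of
real keypress data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .models import FAMILIES, TERMS, covariate_coding

#: Column order of the trial table (the on-disk CSV dialect).
TRIAL_COLUMNS = (
    "participant", "block", "trial_in_block", "trial_type",
    "foreperiod_ms", "rt_ms", "accuracy", "iti_ms",
)


@dataclass(frozen=True)
class EffectParams:
    """True effect structure of a simulated experiment.

    ``alpha`` is a 4x3 array of coefficients: rows are the effect families
    (Baseline, CF, FS, IN), columns are (intercept in ms, trial slope in
    ms/trial, block slope in ms/block).  ``sigma_participant`` is the SD of
    participant baseline intercepts around the group mean; residual noise is
    Normal(0, sigma_residual).  Outliers replace the model RT with a draw
    from a fast/slow contamination mixture at rate ``p_outlier``.
    """

    alpha: np.ndarray
    sigma_participant: float = 40.0
    sigma_residual: float = 60.0
    p_error: float = 0.04
    p_outlier: float = 0.02
    n_participants: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (4, 3):
            raise ValueError(f"alpha must be 4x3 (families x terms), got {a.shape}")
        object.__setattr__(self, "alpha", a)
        if self.sigma_participant < 0:
            raise ValueError("sigma_participant must be >= 0")
        if self.sigma_residual <= 0:
            raise ValueError("sigma_residual must be > 0")
        if not 0 <= self.p_error < 1:
            raise ValueError("p_error must be in [0, 1)")
        if not 0 <= self.p_outlier < 1:
            raise ValueError("p_outlier must be in [0, 1)")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    @classmethod
    def from_dict(cls, coefficients: dict[str, float], **kwargs) -> "EffectParams":
        """Build from ``{"FS.intercept": 15.0, ...}``; missing terms are 0."""
        a = np.zeros((4, 3))
        for name, value in coefficients.items():
            fam, term = name.split(".")
            a[FAMILIES.index(fam), TERMS.index(term)] = value
        return cls(alpha=a, **kwargs)

    def coefficient(self, name: str) -> float:
        fam, term = name.split(".")
        return float(self.alpha[FAMILIES.index(fam), TERMS.index(term)])

    def as_dict(self) -> dict[str, float]:
        return {
            f"{fam}.{term}": float(self.alpha[i, j])
            for i, fam in enumerate(FAMILIES)
            for j, term in enumerate(TERMS)
        }


def mean_rt(
    params: EffectParams,
    current: str,
    previous: str,
    t: int,
    b: int,
    participant_offset: float = 0.0,
) -> float:
    """Model mean RT for one design cell at trial t of block b.

    ``current`` / ``previous`` are ``"short"`` or ``"long"``; ``t`` counts
    previous presented trials within the block and ``b`` previous blocks.
    """
    if t < 0 or b < 0:
        raise ValueError("t and b must be >= 0")
    x_cf, x_fs, x_in = covariate_coding(current, previous)
    xs = (1.0, x_cf, x_fs, x_in)
    mu = participant_offset
    for i in range(4):
        beta = params.alpha[i, 0] + params.alpha[i, 1] * t + params.alpha[i, 2] * b
        mu += xs[i] * beta
    return float(mu)


def generate_sequence(
    design: ExperimentDesign,
    rng: np.random.Generator,
    practice: bool = False,
) -> pd.DataFrame:
    """One block's trial skeletons: type, foreperiod and ITI, in random order.

    Exactly the design's counts of short / long / catch trials, uniformly
    shuffled; ITIs drawn uniformly on [iti_min, iti_max].  RT columns are
    left unset.
    """
    if practice:
        n_s, n_l, n_c = design.practice_mix
    else:
        n_s, n_l, n_c = (design.n_short_per_block, design.n_long_per_block,
                         design.n_catch_per_block)
    fps = np.array(
        [design.fp_short] * n_s + [design.fp_long] * n_l + [np.nan] * n_c,
        dtype=float,
    )
    rng.shuffle(fps)
    n = fps.size
    return pd.DataFrame({
        "trial_in_block": np.arange(n),
        "trial_type": np.where(np.isnan(fps), "catch", "regular"),
        "foreperiod_ms": fps,
        "iti_ms": rng.uniform(design.iti_min, design.iti_max, size=n).round(1),
    })


def _draw_outlier(rng: np.random.Generator) -> float:
    """Contaminant RT: half anticipations in [0, 100), half lapses in (1000, 2500]."""
    if rng.uniform() < 0.5:
        return float(rng.uniform(0.0, 100.0))
    return float(rng.uniform(1000.0, 2500.0))


def simulate_experiment(
    design: ExperimentDesign, params: EffectParams
) -> pd.DataFrame:
    """Simulate a full experiment; fully reproducible from ``params.seed``.

    Each participant receives a baseline offset ~ Normal(0,
    sigma_participant).  Regular-trial RT is mean_rt + Normal(0,
    sigma_residual); the first presented trial of a block, and any trial
    following a catch trial, has no previous-foreperiod context and is
    generated from the baseline and current-foreperiod terms only.  Catch
    trials produce no RT.  Practice blocks (block = -1) are generated only
    when the design requests them.
    """
    rng = np.random.default_rng(params.seed)
    short, long_ = float(design.fp_short), float(design.fp_long)
    rows: list[pd.DataFrame] = []
    for p in range(params.n_participants):
        offset = rng.normal(0.0, params.sigma_participant)
        blocks: list[tuple[int, bool]] = []
        if design.practice_included and sum(design.practice_mix) > 0:
            blocks.append((-1, True))
        blocks.extend((i, False) for i in range(design.n_test_blocks))
        for block_idx, is_practice in blocks:
            blk = generate_sequence(design, rng, practice=is_practice)
            n = len(blk)
            rt = np.full(n, np.nan)
            acc = np.full(n, "", dtype=object)
            prev_fp = np.nan  # fp of immediately preceding presented trial
            have_prev = False
            for i in range(n):
                fp = blk["foreperiod_ms"].iat[i]
                if np.isnan(fp):  # catch: no stimulus, no response
                    prev_fp, have_prev = np.nan, True
                    continue
                cur = "short" if fp == short else "long"
                if not have_prev or np.isnan(prev_fp):
                    # no usable context: baseline + current-foreperiod only
                    x_cf = 1 if cur == "long" else 0
                    t, b = i, max(block_idx, 0)
                    mu = offset
                    mu += (params.alpha[0, 0] + params.alpha[0, 1] * t
                           + params.alpha[0, 2] * b)
                    mu += x_cf * (params.alpha[1, 0] + params.alpha[1, 1] * t
                                  + params.alpha[1, 2] * b)
                else:
                    prev = "short" if prev_fp == short else "long"
                    mu = mean_rt(params, cur, prev, i, max(block_idx, 0), offset)
                if params.p_outlier > 0 and rng.uniform() < params.p_outlier:
                    rt[i] = _draw_outlier(rng)
                else:
                    rt[i] = mu + rng.normal(0.0, params.sigma_residual)
                acc[i] = ("error" if params.p_error > 0
                          and rng.uniform() < params.p_error else "correct")
                prev_fp, have_prev = fp, True
            blk = blk.copy()
            blk.insert(0, "participant", p)
            blk.insert(1, "block", block_idx)
            blk["rt_ms"] = np.round(rt, 3)
            blk["accuracy"] = acc
            rows.append(blk)
    table = pd.concat(rows, ignore_index=True)
    table.loc[table["trial_type"] == "catch", "accuracy"] = ""
    return table[list(TRIAL_COLUMNS)]
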