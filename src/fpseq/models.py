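"""Model family for the time-varying decomposition of foreperiod effects.

The trial-level model writes RT as the sum of four effect families —
baseline (B), current foreperiod (CF), the priming component of the
sequential foreperiod effect (FS, repetition vs. alternation) and its
arousal component (IN, previous foreperiod short vs. long):

    RT(t+1, b+1) = beta_B + beta_CF * x_cf + beta_FS * x_fs + beta_IN * x_in

with each beta a linear function of the number of previous trials within
the block (t) and the number of previous blocks (b):

    beta = alpha_0 + alpha_trial * t + alpha_block * b

Covariate coding (fixed package-wide):

    x_cf = 1 if the current foreperiod is long, else 0
    x_fs = 1 if the current and previous foreperiods differ (alternation)
    x_in = -1 if the previous foreperiod was long, else 0

Under this coding the short-foreperiod repetition cell is the baseline,
positive CF means RT was shorter at the short foreperiod, positive FS means
a repetition benefit, and negative IN means faster responses after a short
previous foreperiod.  The sequence effect (alternation minus repetition RT)
equals FS - IN at the short foreperiod and FS + IN at the long one.

Only the baseline intercept varies across participants; every other
coefficient is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FAMILIES = ("Baseline", "CF", "FS", "IN")
TERMS = ("intercept", "trial", "block")

#: All 12 coefficient names, in reporting order.
ALL_TERMS: tuple[str, ...] = tuple(
    f"{fam}.{term}" for fam in FAMILIES for term in TERMS
)

#: The 11 regression coefficients that enter the design matrix; the baseline
#: intercept is the hierarchical participant-level mean and is handled apart.
REGRESSION_TERMS: tuple[str, ...] = tuple(
    t for t in ALL_TERMS if t != "Baseline.intercept"
)


def covariate_coding(current: str, previous: str) -> tuple[int, int, int]:
    """(x_cf, x_fs, x_in) for a cell given current/previous foreperiod length.

    ``current`` and ``previous`` are ``"short"`` or ``"long"``.
    """
    for v in (current, previous):
        if v not in ("short", "long"):
            raise ValueError(f"foreperiod length must be 'short' or 'long', got {v!r}")
    x_cf = 1 if current == "long" else 0
    x_fs = 1 if current != previous else 0
    x_in = -1 if previous == "long" else 0
    return x_cf, x_fs, x_in


# ---------------------------------------------------------------------------
# Cell-mean algebra (at t = b = 0, intercepts only)
# ---------------------------------------------------------------------------

def cell_means(b0: float, c0: float, f0: float, a0: float) -> dict[str, float]:
    """Map intercepts (B, CF, FS, IN) to the four cell means.

    Cells are named current-then-previous: ``"SS"`` is current short after
    previous short, ``"SL"`` current short after previous long, etc.
    """
    out = {}
    for cell, (cur, prev) in {
        "SS": ("short", "short"), "SL": ("short", "long"),
        "LL": ("long", "long"), "LS": ("long", "short"),
    }.items():
        x_cf, x_fs, x_in = covariate_coding(cur, prev)
        out[cell] = b0 + c0 * x_cf + f0 * x_fs + a0 * x_in
    return out


def coefficients_from_cell_means(
    ss: float, sl: float, ll: float, ls: float
) -> tuple[float, float, float, float]:
    """Inverse of :func:`cell_means`; returns (B, CF, FS, IN) intercepts."""
    b0 = ss
    f0 = ((sl - ss) + (ls - ll)) / 2.0
    a0 = ((ls - ll) - (sl - ss)) / 2.0
    c0 = ll - ss + a0
    return b0, c0, f0, a0


def sfp_effect(f0: float, a0: float, current: str) -> float:
    """Sequence effect (alternation RT minus repetition RT) at a foreperiod."""
    if current == "short":
        return f0 - a0
    if current == "long":
        return f0 + a0
    raise ValueError(f"current must be 'short' or 'long', got {current!r}")


# ---------------------------------------------------------------------------
# Model variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One member of the compared model family.

    ``included_terms`` is a subset of :data:`ALL_TERMS`; excluded
    coefficients are fixed to exactly zero.  The baseline intercept is
    always present and always participant-varying.
    """

    name: str
    included_terms: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.included_terms - set(ALL_TERMS)
        if unknown:
            raise ValueError(f"unknown coefficient names: {sorted(unknown)}")
        if "Baseline.intercept" not in self.included_terms:
            raise ValueError("the baseline intercept cannot be excluded")

    @property
    def regression_terms(self) -> tuple[str, ...]:
        """Included coefficients that enter the design matrix, in order."""
        return tuple(t for t in REGRESSION_TERMS if t in self.included_terms)


def enumerate_variants() -> tuple[ModelSpec, ...]:
    """The five compared variants.

    Model1 carries all 12 coefficients; Model1prime drops the arousal
    intercept; Model2 drops all trial slopes; Model3 all block slopes;
    Model4 keeps intercepts only.
    """
    full = frozenset(ALL_TERMS)
    trial = {t for t in ALL_TERMS if t.endswith(".trial")}
    block = {t for t in ALL_TERMS if t.endswith(".block")}
    return (
        ModelSpec("Model1", full),
        ModelSpec("Model1prime", full - {"IN.intercept"}),
        ModelSpec("Model2", full - trial),
        ModelSpec("Model3", full - block),
        ModelSpec("Model4", full - trial - block),
    )


def get_variant(name: str) -> ModelSpec:
    """Look up one of the five variants by name."""
    for spec in enumerate_variants():
        if spec.name == name:
            return spec
    raise ValueError(
        f"unknown model {name!r}; available: "
        f"{[s.name for s in enumerate_variants()]}"
    )


def linear_predictor(
    spec: ModelSpec,
    coefficients: dict[str, float],
    row: dict[str, float],
    participant_offset: float = 0.0,
) -> float:
    """Mean RT for one observation under a variant.

    ``row`` supplies ``x_cf``, ``x_fs``, ``x_in``, ``t`` and ``b``.
    Coefficients excluded from ``spec`` contribute exactly zero even if
    present in ``coefficients``.
    """
    x = {"Baseline": 1.0, "CF": row["x_cf"], "FS": row["x_fs"], "IN": row["x_in"]}
    t, b = row["t"], row["b"]
    mu = participant_offset
    for fam in FAMILIES:
        for term, scale in (("intercept", 1.0), ("trial", t), ("block", b)):
            name = f"{fam}.{term}"
            if name in spec.included_terms:
                mu += x[fam] * coefficients.get(name, 0.0) * scale
    return mu


# ---------------------------------------------------------------------------
# Priors and the fittable model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Broad, weakly informative priors on the millisecond scale.

    Fixed effects and drift slopes get Normal(0, s_fixed); the group mean of
    the participant baselines gets Normal(baseline_loc, s_baseline) with
    ``baseline_loc`` defaulting to the sample grand mean at build time; group
    and residual SDs get half-Normal(s_sd) / half-Normal(s_residual).
    """

    s_fixed: float = 100.0
    baseline_loc: float | None = None
    s_baseline: float = 200.0
    s_sd: float = 100.0
    s_residual: float = 100.0

    def __post_init__(self) -> None:
        for name in ("s_fixed", "s_baseline", "s_sd", "s_residual"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior scale {name} must be > 0")


@dataclass
class HierarchicalRTModel:
    """A variant bound to data, ready for MCMC.

    Holds the response vector, the design matrix over the variant's
    regression terms, integer participant codes and the resolved priors.
    """

    spec: ModelSpec
    priors: PriorSpec
    y: np.ndarray                      # (n,) RT in ms
    X: np.ndarray                      # (n, p) regressors, column order = terms
    terms: tuple[str, ...]             # regression coefficient names
    participant_index: np.ndarray      # (n,) codes 0..P-1
    participants: tuple                # original participant labels
    baseline_loc: float                # resolved prior location for the group mean

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_participants(self) -> int:
        return len(self.participants)


_DESIGN_COLUMN_OF = {
    "Baseline.trial": "t", "Baseline.block": "b",
    "CF.intercept": "x_cf", "CF.trial": "cf_t", "CF.block": "cf_b",
    "FS.intercept": "x_fs", "FS.trial": "fs_t", "FS.block": "fs_b",
    "IN.intercept": "x_in", "IN.trial": "in_t", "IN.block": "in_b",
}


def build_model(
    spec: ModelSpec, priors: PriorSpec, data: pd.DataFrame
) -> HierarchicalRTModel:
    """Bind a model variant to a design-row table.

    ``data`` is the output of :func:`fpseq.preprocess.build_design_rows`.
    The likelihood is rt ~ Normal(mu, sigma_residual) with participant
    baseline intercepts drawn from a common Normal whose mean and SD are
    estimated; all other coefficients are shared across participants.
    """
    if len(data) == 0:
        raise ValueError("cannot build a model on an empty design matrix")
    labels, codes = np.unique(data["participant"].to_numpy(), return_inverse=True)
    if labels.size < 2:
        raise ValueError(
            "hierarchical baseline needs >= 2 participants; "
            "fit a flat (non-hierarchical) baseline for single-participant data"
        )
    terms = spec.regression_terms
    X = data[[_DESIGN_COLUMN_OF[t] for t in terms]].to_numpy(dtype=float)
    y = data["rt"].to_numpy(dtype=float)
    loc = float(np.mean(y)) if priors.baseline_loc is None else priors.baseline_loc
    return HierarchicalRTModel(
        spec=spec, priors=priors, y=y, X=X, terms=terms,
        participant_index=codes.astype(np.intp),
        participants=tuple(labels.tolist()), baseline_loc=loc,
    )
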