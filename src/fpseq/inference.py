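"""MCMC fitting and decision statistics.

The posterior of the hierarchical RT model is sampled by a blocked Gibbs
scheme that exploits its conditional conjugacy:

* shared regression coefficients — joint multivariate-Normal conditional;
* participant baseline intercepts — independent Normal conditionals
  (centred parameterisation: intercepts ~ Normal(group mean, group SD));
* group baseline mean — Normal conditional;
* group and residual SDs (half-Normal priors) — univariate slice sampling.

Decision statistics follow the HDI+ROPE convention: a coefficient is judged
nonzero when its 95% highest-density interval lies wholly outside a region
of practical equivalence of +/-0.1 posterior SDs around zero.  Models are
compared by WAIC with pointwise standard errors and Akaike weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ALL_TERMS, HierarchicalRTModel, ModelSpec

log = logging.getLogger(__name__)

_RHAT_LIMIT = 1.05


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _slice_sample_positive(logpost, x0: float, rng: np.random.Generator,
                           w: float, max_steps: int = 100) -> float:
    """One slice-sampling update of a positive scalar (stepping out + shrink)."""
    logy = logpost(x0) - rng.exponential()
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 - w * u + w
    steps = max_steps
    while lo > 0 and steps > 0 and logpost(lo) > logy:
        lo -= w
        steps -= 1
    lo = max(lo, 1e-12)
    steps = max_steps
    while steps > 0 and logpost(hi) > logy:
        hi += w
        steps -= 1
    while True:
        x1 = rng.uniform(lo, hi)
        if logpost(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


@dataclass
class PosteriorFit:
    """Posterior draws for one fitted model variant.

    Coefficient draws have shape (chains, samples); ``baseline_mean`` is the
    group mean of the participant intercepts and is reported under the name
    ``Baseline.intercept``.
    """

    model: HierarchicalRTModel
    coef: dict[str, np.ndarray]           # term -> (chains, samples)
    baseline_mean: np.ndarray             # (chains, samples)
    participant_intercepts: np.ndarray    # (chains, samples, P)
    sigma_participant: np.ndarray         # (chains, samples)
    sigma_residual: np.ndarray            # (chains, samples)
    seed: int
    diagnostics: pd.DataFrame = field(default=None, repr=False)
    flagged: bool = False

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return ("Baseline.intercept",) + tuple(self.model.terms)

    def draws(self, name: str) -> np.ndarray:
        """Flattened posterior draws for a named parameter."""
        if name == "Baseline.intercept":
            return self.baseline_mean.ravel()
        if name == "sigma_participant":
            return self.sigma_participant.ravel()
        if name == "sigma_residual":
            return self.sigma_residual.ravel()
        if name in self.coef:
            return self.coef[name].ravel()
        raise KeyError(f"parameter {name!r} not in model {self.model.spec.name}")

    def pointwise_loglik(self, chunk: int = 256) -> np.ndarray:
        """Per-observation log-likelihood matrix, shape (n_obs, n_draws)."""
        m = self.model
        theta = np.stack(
            [self.coef[t].ravel() for t in m.terms], axis=0
        ) if m.terms else np.zeros((0, self.baseline_mean.size))
        a = self.participant_intercepts.reshape(-1, m.n_participants)
        sig = self.sigma_residual.ravel()
        n_draws = sig.size
        out = np.empty((m.n_obs, n_draws))
        for s in range(0, n_draws, chunk):
            e = min(s + chunk, n_draws)
            mu = m.X @ theta[:, s:e] + a[s:e, :].T[m.participant_index, :]
            z = (m.y[:, None] - mu) / sig[None, s:e]
            out[:, s:e] = -0.5 * z * z - np.log(sig[None, s:e]) \
                - 0.5 * math.log(2.0 * math.pi)
        return out


def _run_chain(model: HierarchicalRTModel, warmup: int, samples: int,
               rng: np.random.Generator):
    """One Gibbs chain.

    The coefficient block (group baseline mean + shared regression
    coefficients) is updated with the participant intercepts integrated
    out; the marginal covariance is block diagonal per participant, so the
    Woodbury correction reduces to per-participant column sums of the
    design matrix.  This collapsed update decorrelates the coefficients
    from the intercepts and mixes close to independently.
    """
    y, X, pidx = model.y, model.X, model.participant_index
    n, p = X.shape
    P = model.n_participants
    pr = model.priors
    counts = np.bincount(pidx, minlength=P).astype(float)

    Xt = np.column_stack([np.ones(n), X])       # [baseline mean | coefficients]
    q = p + 1
    XtX = Xt.T @ Xt
    Xty = Xt.T @ y
    # per-participant column sums of the extended design and of y
    S = np.stack([np.bincount(pidx, weights=Xt[:, j], minlength=P)
                  for j in range(q)], axis=1)   # (P, q)
    ysum = np.bincount(pidx, weights=y, minlength=P)
    prior_prec = np.concatenate([[1.0 / pr.s_baseline**2],
                                 np.full(p, 1.0 / pr.s_fixed**2)])
    prior_mean = np.concatenate([[model.baseline_loc], np.zeros(p)])

    part_mean = ysum / counts
    a = part_mean.copy()
    beta = np.zeros(q)
    beta[0] = float(np.mean(y))
    sig_p = max(float(np.std(part_mean)), 1.0)
    sig_r = max(float(np.std(y - a[pidx])), 1.0)

    keep_beta = np.empty((samples, q))
    keep_a = np.empty((samples, P))
    keep_sp = np.empty(samples)
    keep_sr = np.empty(samples)

    for it in range(warmup + samples):
        # (group mean, coefficients) | SDs, intercepts integrated out:
        # V = sig_r^2 I + sig_p^2 Z Z', block diagonal per participant
        c = sig_p**2 / (sig_r**2 * (sig_r**2 + counts * sig_p**2))  # (P,)
        prec = XtX / sig_r**2 - (S.T * c) @ S + np.diag(prior_prec)
        rhs = Xty / sig_r**2 - S.T @ (c * ysum) + prior_prec * prior_mean
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(q))
        b0 = beta[0]
        resid = y - X @ beta[1:]                 # y minus shared effects
        rsum = np.bincount(pidx, weights=resid, minlength=P)
        # participant intercepts | coefficients, group mean, SDs
        prec_a = counts / sig_r**2 + 1.0 / sig_p**2
        mean_a = (rsum / sig_r**2 + b0 / sig_p**2) / prec_a
        a = mean_a + rng.standard_normal(P) / np.sqrt(prec_a)
        # group SD of intercepts (half-Normal prior) via slice sampling
        ssa = float(np.sum((a - b0) ** 2))
        sig_p = _slice_sample_positive(
            lambda s: -P * math.log(s) - ssa / (2 * s * s) - s * s / (2 * pr.s_sd**2),
            sig_p, rng, w=max(sig_p / 2, 1.0))
        # residual SD | everything else
        ssr = float(np.sum((resid - a[pidx]) ** 2))
        sig_r = _slice_sample_positive(
            lambda s: -n * math.log(s) - ssr / (2 * s * s)
            - s * s / (2 * pr.s_residual**2),
            sig_r, rng, w=max(sig_r / 10, 1.0))

        if it >= warmup:
            k = it - warmup
            keep_beta[k] = beta
            keep_a[k] = a
            keep_sp[k] = sig_p
            keep_sr[k] = sig_r
    return keep_beta[:, 1:], keep_beta[:, 0], keep_a, keep_sp, keep_sr


def fit(model: HierarchicalRTModel, chains: int = 4, warmup: int = 1000,
        samples: int = 1000, seed: int = 0) -> PosteriorFit:
    """Sample the posterior by blocked Gibbs; reproducible from ``seed``.

    Split-R-hat and bulk effective sample size (computed with arviz) are
    attached for every shared coefficient; the fit is flagged when any
    R-hat exceeds 1.05.
    """
    if chains < 2:
        raise ValueError("need >= 2 chains for split-R-hat diagnostics")
    p = len(model.terms)
    streams = np.random.SeedSequence(seed).spawn(chains)
    th = np.empty((chains, samples, p))
    b0 = np.empty((chains, samples))
    a = np.empty((chains, samples, model.n_participants))
    sp = np.empty((chains, samples))
    sr = np.empty((chains, samples))
    for c, ss in enumerate(streams):
        th[c], b0[c], a[c], sp[c], sr[c] = _run_chain(
            model, warmup, samples, np.random.default_rng(ss))
    coef = {t: th[:, :, j] for j, t in enumerate(model.terms)}
    fit_ = PosteriorFit(
        model=model, coef=coef, baseline_mean=b0, participant_intercepts=a,
        sigma_participant=sp, sigma_residual=sr, seed=seed)
    fit_.diagnostics = _diagnostics(fit_)
    fit_.flagged = bool((fit_.diagnostics["rhat"] > _RHAT_LIMIT).any())
    if fit_.flagged:
        log.warning("fit of %s flagged: max R-hat %.3f", model.spec.name,
                    fit_.diagnostics["rhat"].max())
    return fit_


def _diagnostics(fit_: PosteriorFit) -> pd.DataFrame:
    import arviz as az

    data = {t: fit_.coef[t] for t in fit_.model.terms}
    data["Baseline.intercept"] = fit_.baseline_mean
    data["sigma_participant"] = fit_.sigma_participant
    data["sigma_residual"] = fit_.sigma_residual
    idata = az.from_dict(posterior=data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = [{"parameter": k, "rhat": float(rhat[k].values),
             "ess_bulk": float(ess[k].values)} for k in data]
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# HDI + ROPE decisions
# ---------------------------------------------------------------------------

def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 draws for an HDI, got {n}")
    k = int(math.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def rope_bounds(sd: float, multiplier: float = 0.1) -> tuple[float, float]:
    """Region of practical equivalence: +/- ``multiplier`` posterior SDs.

    The multiplier 0.1 is half of the conventional small-effect size,
    applied on the scale of the parameter's own posterior SD.
    """
    if sd < 0:
        raise ValueError("posterior SD must be >= 0")
    return (-multiplier * sd, multiplier * sd)


def decide(hdi95: tuple[float, float], rope: tuple[float, float]) -> str:
    """``"reject_zero"`` iff the HDI lies completely outside the ROPE."""
    (hl, hh), (rl, rh) = hdi95, rope
    if hl > hh or rl > rh:
        raise ValueError("intervals must be ordered (low, high)")
    return "reject_zero" if (hh < rl or hl > rh) else "not_rejected"


@dataclass(frozen=True)
class PosteriorSummary:
    """One summary-table row: mean, SD, ROPE, 95% HDI and the decision."""

    parameter: str
    mean: float | None
    sd: float | None
    rope: tuple[float, float] | None
    hdi95: tuple[float, float] | None
    decision: str  # reject_zero | not_rejected | not_in_model


#: Reporting order of the published summary tables (baseline intercept is a
#: participant-level quantity and is not tabulated).
TABLE_ORDER = (
    "Baseline.trial", "Baseline.block",
    "CF.intercept", "CF.trial", "CF.block",
    "FS.intercept", "FS.trial", "FS.block",
    "IN.intercept", "IN.trial", "IN.block",
)


def summarize(fit_: PosteriorFit, mass: float = 0.95) -> list[PosteriorSummary]:
    """Posterior summary rows in table order; absent terms marked."""
    rows = []
    for name in TABLE_ORDER:
        if name not in fit_.model.terms:
            rows.append(PosteriorSummary(name, None, None, None, None,
                                         "not_in_model"))
            continue
        d = fit_.draws(name)
        sd = float(np.std(d, ddof=1))
        interval = hdi(d, mass)
        rope = rope_bounds(sd)
        rows.append(PosteriorSummary(
            name, float(np.mean(d)), sd, rope, interval,
            decide(interval, rope)))
    return rows


def summary_frame(rows: list[PosteriorSummary]) -> pd.DataFrame:
    """Summary rows as a DataFrame mirroring the published column order."""
    return pd.DataFrame([{
        "parameter": r.parameter,
        "mean": r.mean,
        "sd": r.sd,
        "rope_low": None if r.rope is None else r.rope[0],
        "rope_high": None if r.rope is None else r.rope[1],
        "hdi_low": None if r.hdi95 is None else r.hdi95[0],
        "hdi_high": None if r.hdi95 is None else r.hdi95[1],
        "reject_zero": {"reject_zero": "Yes", "not_rejected": "No",
                        "not_in_model": "-"}[r.decision],
    } for r in rows])


# ---------------------------------------------------------------------------
# WAIC and model comparison
# ---------------------------------------------------------------------------

def waic(loglik: np.ndarray) -> tuple[float, np.ndarray, float]:
    """WAIC on the deviance scale from an (observations x draws) matrix.

    Returns (WAIC, pointwise contributions, SE).  Per observation,
    lppd_i = log mean_s exp(loglik_is) and the penalty is the across-draw
    variance of the log-likelihood; WAIC = -2 * sum(lppd_i - p_i) with
    SE = sqrt(n * var_i(pointwise)).
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik must be (observations x draws)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik contains non-finite entries")
    n, s = ll.shape
    mx = ll.max(axis=1, keepdims=True)
    lppd = np.log(np.mean(np.exp(ll - mx), axis=1)) + mx[:, 0]
    penalty = ll.var(axis=1)  # population variance: invariant to draw duplication
    pointwise = -2.0 * (lppd - penalty)
    total = float(pointwise.sum())
    se = float(math.sqrt(n * pointwise.var()))
    return total, pointwise, se


@dataclass(frozen=True)
class ComparisonTable:
    """Per-model WAIC, differences to the best model and Akaike weights."""

    table: pd.DataFrame  # index model name; columns waic, se, dwaic, dse,
    #                      dwaic_low, dwaic_high, weight

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def to_json(self, path) -> None:
        self.table.reset_index().to_json(path, orient="records", indent=2)


def compare(waics: dict[str, tuple[float, np.ndarray, float]]) -> ComparisonTable:
    """Rank models by WAIC; differences use paired pointwise contributions.

    The 95% interval of each WAIC difference is dWAIC +/- 1.96 * dSE with
    dSE = sqrt(n * var_i(pointwise_A - pointwise_B)).  Akaike weights are
    exp(-dWAIC/2), normalised.
    """
    if len(waics) < 2:
        raise ValueError("need >= 2 models to compare")
    sizes = {name: len(pw) for name, (_, pw, _) in waics.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"models fitted on different observation sets: {sizes}")
    order = sorted(waics, key=lambda k: waics[k][0])
    best = order[0]
    _, pw_best, _ = waics[best]
    n = pw_best.size
    rows = []
    dws = np.array([waics[m][0] - waics[best][0] for m in order])
    weights = np.exp(-0.5 * dws)
    weights /= weights.sum()
    for m, w in zip(order, weights):
        total, pw, se = waics[m]
        if m == best:
            dw, dse = 0.0, 0.0
        else:
            diff = pw - pw_best
            dw = float(diff.sum())
            dse = float(math.sqrt(n * diff.var()))
        rows.append({"model": m, "waic": total, "se": se, "dwaic": dw,
                     "dse": dse, "dwaic_low": dw - 1.96 * dse,
                     "dwaic_high": dw + 1.96 * dse, "weight": float(w)})
    return ComparisonTable(pd.DataFrame(rows).set_index("model"))


def posterior_probability(
    fit_: PosteriorFit, expression: dict[str, float], direction: str = ">",
    threshold: float = 0.0,
) -> float:
    """Posterior probability that a linear combination of parameters exceeds
    (or falls below) a threshold.

    ``expression`` maps parameter names to weights, e.g. the sequence effect
    at the long foreperiod is ``{"FS.intercept": 1, "IN.intercept": 1}``.
    """
    if direction not in (">", "<"):
        raise ValueError("direction must be '>' or '<'")
    value = None
    for name, w in expression.items():
        d = w * fit_.draws(name)  # KeyError for unknown parameters
        value = d if value is None else value + d
    if value is None:
        raise ValueError("empty expression")
    return float(np.mean(value > threshold if direction == ">"
                         else value < threshold))
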