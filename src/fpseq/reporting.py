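"""End-to-end orchestration, binned effect summaries and parameter recovery.

``binned_sequence_effect`` produces the figure-style summaries: the
sequence effect (alternation RT minus repetition RT, positive = repetition
benefit) per current foreperiod in equal-width bins along the trial-within-
block or block axis, averaged within participants before across them;
participants missing any cell in any bin are dropped and reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ExperimentDesign, design_preset
from .inference import (compare, fit, summarize, summary_frame, waic)
from .models import PriorSpec, build_model, get_variant
from .preprocess import annotate, apply_exclusions, build_design_rows
from .simulate import EffectParams, simulate_experiment
from .io import read_trials, write_trials

log = logging.getLogger(__name__)


def binned_sequence_effect(
    retained: pd.DataFrame, axis: str = "trial", n_bins: int = 4,
) -> tuple[pd.DataFrame, list]:
    """Sequence effect per (bin x current foreperiod).

    Returns the binned table and the list of participants dropped for
    missing at least one (bin x foreperiod x sequence) cell.  Bins are
    equal-width along trial-in-block (``axis="trial"``) or block index
    (``axis="block"``).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if axis not in ("trial", "block"):
        raise ValueError("axis must be 'trial' or 'block'")
    col = "trial_in_block" if axis == "trial" else "block"
    d = retained.copy()
    span = float(d[col].max()) + 1.0
    d["bin"] = np.minimum((d[col] * n_bins / span).astype(int), n_bins - 1)
    d["sequence"] = np.where(d["x_fs"] > 0, "alternation", "repetition")
    cell = (d.groupby(["participant", "bin", "foreperiod_ms", "sequence"],
                      observed=True)["rt_ms"]
            .agg(["mean", "size"]).reset_index())
    # a complete participant has every bin x foreperiod x sequence cell
    n_fp = d["foreperiod_ms"].nunique()
    counts = cell.groupby("participant").size()
    complete = counts[counts == n_bins * n_fp * 2].index
    dropped = sorted(set(cell["participant"]) - set(complete))
    if dropped:
        log.info("binned_sequence_effect: dropped participants %s", dropped)
    cell = cell[cell["participant"].isin(complete)]
    if len(cell) == 0:
        log.warning("binned_sequence_effect: no participant has every cell")
        empty = pd.DataFrame(columns=["axis", "bin", "current_fp", "effect_ms",
                                      "n_trials", "n_participants"])
        return empty, dropped
    wide = cell.pivot_table(index=["participant", "bin", "foreperiod_ms"],
                            columns="sequence", values="mean")
    wide["effect"] = wide["alternation"] - wide["repetition"]
    ntr = cell.groupby(["bin", "foreperiod_ms"], observed=True)["size"].sum()
    out = (wide.groupby(["bin", "foreperiod_ms"])["effect"].mean()
           .reset_index().rename(columns={"foreperiod_ms": "current_fp",
                                          "effect": "effect_ms"}))
    out.insert(0, "axis", axis)
    out["n_trials"] = ntr.values
    out["n_participants"] = len(complete)
    return out, dropped


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    design: str | dict = "exp1"
    effects: dict = field(default_factory=dict)
    input: str | None = None
    rt_low: float = 100.0
    rt_high: float = 1000.0
    models: tuple[str, ...] = ("Model1", "Model4")
    priors: dict = field(default_factory=dict)
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    bins: int = 4
    outdir: str = "fpseq_out"

    def __post_init__(self) -> None:
        for name in self.models:
            get_variant(name)  # raises on unknown model names
        if self.bins < 1:
            raise ValueError("bins must be >= 1")
        self.models = tuple(self.models)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        payload = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls(**payload)

    def resolve_design(self) -> ExperimentDesign:
        if isinstance(self.design, str):
            return design_preset(self.design)
        return ExperimentDesign(**self.design)

    def resolve_effects(self) -> EffectParams:
        eff = dict(self.effects)
        coefs = eff.pop("coefficients", {})
        eff.setdefault("seed", self.seed)
        return EffectParams.from_dict(coefs, **eff)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate-or-load, preprocess, fit, compare, summarise, bin; write all.

    Returns a bundle dict with in-memory results and the paths written.
    Every output directory carries a provenance record (config hash, seed,
    package version).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        design = config.resolve_design()
        if config.input is not None:
            trials = read_trials(config.input)
        else:
            stage = "simulate"
            trials = simulate_experiment(design, config.resolve_effects())
            write_trials(outdir / "trials.csv", trials)
        stage = "preprocess"
        annotated = annotate(trials)
        retained, report = apply_exclusions(
            annotated, config.rt_low, config.rt_high,
            has_catch=design.n_catch_per_block > 0)
        report.to_json(outdir / "exclusion_report.json")
        rows = build_design_rows(retained)
        stage = "fit"
        priors = PriorSpec(**config.priors)
        fits, waics = {}, {}
        for name in config.models:
            model = build_model(get_variant(name), priors, rows)
            f = fit(model, config.chains, config.warmup, config.samples,
                    seed=config.seed)
            fits[name] = f
            waics[name] = waic(f.pointwise_loglik())
            summary_frame(summarize(f)).to_csv(
                outdir / f"summary_{name}.csv", index=False)
        stage = "compare"
        comparison = compare(waics) if len(waics) >= 2 else None
        if comparison is not None:
            comparison.to_json(outdir / "comparison.json")
        stage = "report"
        binned = {}
        for axis in ("trial", "block"):
            table, dropped = binned_sequence_effect(retained, axis, config.bins)
            table.to_csv(outdir / f"binned_{axis}.csv", index=False)
            binned[axis] = (table, dropped)
        provenance = {
            "config_hash": config.digest(), "seed": config.seed,
            "fpseq_version": __version__,
            "numpy_version": np.__version__, "pandas_version": pd.__version__,
            "models": list(config.models),
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2), encoding="utf-8")
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage: {stage}\n{err}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return {"trials": trials, "retained": retained, "exclusions": report,
            "fits": fits, "comparison": comparison, "binned": binned,
            "provenance": provenance, "outdir": outdir}


def recovery_study(
    design: ExperimentDesign, truth: EffectParams, n_replications: int,
    spec_name: str = "Model1", chains: int = 2, warmup: int = 500,
    samples: int = 500, seed: int = 0, priors: PriorSpec | None = None,
) -> pd.DataFrame:
    """Repeated simulate-and-refit: bias, HDI coverage and decisions.

    Per coefficient: mean posterior-mean bias against the generating value,
    empirical 95%-HDI coverage of the truth, and the fraction of
    replications rejecting zero.
    """
    if n_replications < 2:
        raise ValueError("n_replications must be >= 2")
    priors = priors or PriorSpec()
    spec = get_variant(spec_name)
    truth_map = truth.as_dict()
    records: list[dict] = []
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(2 * n_replications) % (2**31)
    for r in range(n_replications):
        params = EffectParams(
            alpha=truth.alpha, sigma_participant=truth.sigma_participant,
            sigma_residual=truth.sigma_residual, p_error=truth.p_error,
            p_outlier=truth.p_outlier, n_participants=truth.n_participants,
            seed=int(rep_seeds[2 * r]))
        trials = simulate_experiment(design, params)
        retained, _ = apply_exclusions(
            annotate(trials), has_catch=design.n_catch_per_block > 0)
        rows = build_design_rows(retained)
        f = fit(build_model(spec, priors, rows), chains, warmup, samples,
                seed=int(rep_seeds[2 * r + 1]))
        for s in summarize(f):
            if s.decision == "not_in_model":
                continue
            true_val = truth_map[s.parameter]
            records.append({
                "replication": r, "parameter": s.parameter, "true": true_val,
                "posterior_mean": s.mean, "bias": s.mean - true_val,
                "covered": s.hdi95[0] <= true_val <= s.hdi95[1],
                "reject_zero": s.decision == "reject_zero",
                "sign_correct": np.sign(s.mean) == np.sign(true_val)
                if true_val != 0 else None,
            })
    per_rep = pd.DataFrame(records)
    out = per_rep.groupby("parameter").agg(
        true=("true", "first"), mean_bias=("bias", "mean"),
        coverage=("covered", "mean"), reject_rate=("reject_zero", "mean"),
    ).reset_index()
    out.attrs["per_replication"] = per_rep
    return out
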