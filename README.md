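# fpseq

Trial-level Bayesian analysis of **variable-foreperiod** reaction-time
experiments: simulation, exclusion rules, time-varying hierarchical models of
the sequential foreperiod effect, WAIC model comparison, and HDI+ROPE
parameter decisions.

## The scientific problem

In a variable-foreperiod task a warning signal precedes an imperative
stimulus by a randomly varying interval (the *foreperiod*, FP).  Reaction
time depends not only on the current foreperiod but on the previous one —
the **sequential foreperiod (SFP) effect**.  Competing accounts make
different predictions: a *repetition-priming* account predicts a symmetric
repetition benefit; an *arousal* account predicts a cost of a long previous
foreperiod everywhere; trace-based preparation theories predict both at
once, producing the classic asymmetric pattern (large SFP effect at short
current FPs, none at long ones).

`fpseq` decomposes trial-level RT additively into four effect families —
baseline (B), current foreperiod (CF), the priming component of the SFP
effect (FS) and its arousal component (IN) — and lets every family drift
linearly over the experiment:

```
RT(t+1, b+1) = beta_B + beta_CF * x_cf + beta_FS * x_fs + beta_IN * x_in
beta         = alpha_0 + alpha_trial * t + alpha_block * b
```

where `t` counts previous trials within the block, `b` previous blocks, and
the covariates are `x_cf = 1{current FP long}`, `x_fs = 1{FP alternation}`,
`x_in = -1{previous FP long}`.  The short-FP repetition cell is the
baseline; only the baseline intercept varies across participants (a Normal
hierarchy); the likelihood is Normal on the millisecond scale.  Under this
coding the SFP effect equals `FS - IN` at the short and `FS + IN` at the
long foreperiod, so "FS > 0 and IN < 0 of similar size" is exactly the
asymmetric pattern.

Five nested variants are compared by WAIC (Model1 = all 12 coefficients,
Model1prime drops the arousal intercept, Model2 all trial slopes, Model3
all block slopes, Model4 keeps intercepts only).  Each coefficient is
judged nonzero when its 95% highest-density interval lies wholly outside a
region of practical equivalence of ±0.1 posterior SDs around zero.

The package ships a generative twin of the fitted model (two-FP designs
with catch trials and non-aging or uniform mixes, participant-varying
baselines, drift, response errors and RT outliers), the published exclusion
rules (RT < 100 ms or > 1000 ms, first trial of each block, trials after an
error or a catch trial), a collapsed Gibbs sampler for the hierarchy, and a
parameter-recovery harness.  It is written for researchers who want to run
this analysis on their own trial tables or probe its operating
characteristics by simulation.

## Worked example

```python
import fpseq as fq

design = fq.ExperimentDesign(fp_short=400, fp_long=1400, n_short_per_block=12,
                             n_long_per_block=12, n_catch_per_block=0,
                             n_test_blocks=5)
params = fq.EffectParams.from_dict(
    {"Baseline.intercept": 330.0, "FS.intercept": 15.0, "IN.intercept": -15.0},
    n_participants=8, sigma_residual=60.0, seed=42)
trials = fq.simulate_experiment(design, params)
retained, report = fq.apply_exclusions(fq.annotate(trials), has_catch=False)
print(f"retained {len(retained)} of {report.n_regular_presented} regular trials "
      f"({report.proportion_excluded:.1%} excluded)")
rows = fq.build_design_rows(retained)
fit = fq.fit(fq.build_model(fq.get_variant("Model4"), fq.PriorSpec(), rows),
             chains=2, warmup=300, samples=400, seed=42)
print(fq.summary_frame(fq.summarize(fit)).dropna().round(2).to_string(index=False))
prob = fq.posterior_probability(fit, {"FS.intercept": 1, "IN.intercept": 1}, ">")
print(f"P(repetition benefit at the long foreperiod) = {prob:.2f}")
```

prints

```
retained 861 of 960 regular trials (10.3% excluded)
   parameter  mean   sd  rope_low  rope_high  hdi_low  hdi_high reject_zero
CF.intercept -0.86 3.97     -0.40       0.40    -8.98      6.61          No
FS.intercept 17.77 3.91     -0.39       0.39    10.70     25.89         Yes
IN.intercept -9.36 3.90     -0.39       0.39   -16.51     -1.37         Yes
P(repetition benefit at the long foreperiod) = 0.93
```

The generating truth (FS = 15, IN = −15, CF = 0 at `t = b = 0`) is
recovered within posterior uncertainty: both SFP components are flagged
nonzero with the correct signs — the asymmetric pattern — while the
current-foreperiod effect is not.  At this small simulated size (8
participants, 5 blocks) posterior SDs are ~4 ms and the long-FP sequence
effect (`FS + IN`, truth 0) is still sign-uncertain.

The same pipeline runs from the shell:

```bash
fpseq simulate -c config.yaml -o trials.csv
fpseq preprocess -c config.yaml -t trials.csv -o out/
fpseq fit -c config.yaml -t trials.csv -m Model1prime -o out/summary.csv
fpseq report -c config.yaml       # full pipeline into the config's outdir
fpseq recover -c config.yaml -n 10 -m Model1 -o recovery.csv
```

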