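# Methods

## Model

One row per retained trial, with RT in milliseconds:

```
rt_i ~ Normal(mu_i, sigma_res)
mu_i = a_{p(i)} + sum_{f in {B, CF, FS, IN}} x_f,i * (alpha0_f + alphaT_f * t_i + alphaB_f * b_i)
a_p  ~ Normal(B0, sigma_part)            # participant baseline intercepts
```

`t_i` counts previous presented trials (catch trials included) within the
block, `b_i` previous test blocks; both enter uncentered, so every
intercept is the "short-term" value at the start of the experiment
(`t = b = 0`).  The covariates are fixed package-wide:

| family | covariate | meaning of a positive coefficient |
|---|---|---|
| B (baseline) | 1 | RT in the short-FP repetition cell |
| CF | `1{current FP long}` | RT shorter at the short FP |
| FS (priming) | `1{alternation}` | repetition benefit |
| IN (arousal) | `-1{previous FP long}` | (negative coefficient:) faster after a short previous FP |

This coding makes the short-FP repetition cell the baseline and yields the
identities `SFP(short) = FS - IN`, `SFP(long) = FS + IN` (sequence effect =
alternation minus repetition RT).  The four intercepts map bijectively to
the four cell means at `t = b = 0`; `models.cell_means` /
`models.coefficients_from_cell_means` implement the map and its inverse.
A pure-arousal pattern (previous-long slower everywhere by `a`) corresponds
to `FS = 0, IN = -a`; a pure repetition benefit `p` to `IN = 0, FS = p`;
both nonzero with similar magnitudes and opposite signs give the asymmetric
pattern.

Five variants are compared: `Model1` (all 12 coefficients), `Model1prime`
(no arousal intercept), `Model2` (no trial slopes), `Model3` (no block
slopes), `Model4` (intercepts only).  Only the baseline intercept is
hierarchical; all other coefficients are shared — matching the analysis
design this package reimplements.

## Priors

"Broad on the millisecond scale", made concrete as:

* shared coefficients and drift slopes: `Normal(0, 100 ms)`;
* group baseline mean: `Normal(m, 200 ms)` with `m` the sample grand mean
  at build time (a location-only empirical anchor; the 200 ms scale keeps
  it weak);
* participant-SD and residual-SD: `half-Normal(100 ms)`.

At the sample sizes involved (thousands of trials) the posterior is
data-dominated; `tests/test_reporting.py::test_prior_scale_robustness`
verifies that doubling every scale moves the FS intercept by less than a
third of its posterior SD.

## Sampler

The model is conditionally conjugate, so `inference.fit` uses a blocked
Gibbs scheme rather than a generic gradient sampler:

1. **(group mean, shared coefficients)** jointly, with the participant
   intercepts integrated out.  The marginal covariance
   `sigma_res^2 I + sigma_part^2 Z Z'` is block diagonal per participant,
   so the Woodbury correction needs only per-participant column sums of the
   design matrix; the update is an exact multivariate-Normal draw.
2. **participant intercepts**: independent Normal conditionals.
3. **the two SDs** (half-Normal priors): univariate slice sampling
   (stepping-out and shrinkage) on the positive axis; the sufficient
   statistics are precomputed, so each density evaluation is O(1).

The collapsed coefficient update removes the intercept–slope random-walk
that plagues the centered parameterisation: bulk ESS for reported
coefficients is close to the number of kept draws and split-R-hat ≈ 1.00.
Defaults are 4 chains × (1000 warmup + 1000 kept); tests and the recovery
harness use 2 chains × (500 + 500), which this sampler's mixing makes
ample.  Chains are seeded via `numpy.random.SeedSequence(seed).spawn`, so a
fit is bit-reproducible from its seed.  A fit is flagged when any
split-R-hat (computed with arviz) exceeds 1.05.  An independent check fits
the same posterior with an affine-invariant ensemble sampler (emcee) on a
small dataset and compares posterior means.

## Decision statistics

* **HDI**: shortest contiguous window containing `ceil(0.95 n)` sorted
  draws.  Sample-based; no density smoothing.  Nesting across masses holds
  for unimodal draw sets but is not guaranteed for multimodal ones (the
  shortest window can jump between modes).
* **ROPE**: ±0.1 × the parameter's own posterior SD — half of the
  conventional small-effect size, on the parameter's own scale.  A
  coefficient is "nonzero" when HDI and ROPE are disjoint (strict; touching
  endpoints count as overlap).
* **WAIC**: `-2 * sum_i (lppd_i - p_i)` with `p_i` the across-draw
  *population* variance of the log-likelihood (invariant to duplicating
  draws, and identical to arviz's deviance-scale WAIC);
  `SE = sqrt(n * var_i(pointwise))`.  Differences between models use paired
  pointwise contributions; the 95% interval of a difference is
  `dWAIC ± 1.96 dSE`.  Akaike weights are `exp(-dWAIC/2)`, normalised.

## Synthetic data generator

The generator is the exact generative twin of the fitted model, with the
published design presets: non-aging mixes of 16 short / 8 long / 8 catch
per 32-trial block (FP pairs 400/1400, 50/200, 50/400 ms; catch blank one
second longer than the long FP; 15, 15 and 17 test blocks) and a uniform
12/12 mix per 24-trial block (400/1400 ms, 15 blocks).  Non-aging mixes
have a flat hazard profile (0.5, 0.5); the uniform mix has (0.5, 1.0);
`design.hazard_profile` computes these from the counts.

Defaults beyond the published design numbers, chosen once as typical of
choice-RT data of this kind: participant-baseline SD 40 ms, residual SD
60 ms, error rate 4%, outlier rate 2% (a mixture of anticipations
< 100 ms and lapses in (1000, 2500] ms).  With these defaults the exp4
preset yields ~10% excluded regular trials and the catch-trial presets
~31%, in the range reported for the experiments the presets mirror (the
catch-design exclusions are dominated by the post-catch rule).  ITIs are
drawn uniformly on [500, 1500] ms for fidelity but have no effect on RT.

Deliberate simplifications — and hence what passing tests do *not* show
about real data: residual noise is Gaussian, not right-skewed; error
trials draw RT from the same distribution as correct ones; drift is exactly
linear; there are no lapses in attention beyond the outlier mixture, no
learning curves within the practice block, and no autocorrelated noise.
Trials with no usable previous-trial context (first of a block, after a
catch trial) are generated from the baseline and current-FP terms only;
those trials are excluded from fitting anyway.  Practice blocks are
generated with block index −1 and dropped by preprocessing.

## Preprocessing conventions

* Outlier bounds are exclusive: RT exactly 100 or 1000 ms is retained.
* `t = trial_in_block` counts all presented trials including catch trials.
* Post-error/post-catch rules look back exactly one presented trial.
* Exclusion-report attribution is first-match in the order rt_low,
  rt_high, first_of_block, post_error, post_catch; only the report depends
  on this order, never the retained set.
* Trials following a retained-rule outlier (but correct) response are kept.
* In catch-free designs the catch rules are inert (`has_catch=False`).

## Figure-style binned summaries

`binned_sequence_effect` partitions retained trials into equal-width bins
along trial-in-block or block index and reports, per bin × current FP, the
participant-mean alternation-minus-repetition RT difference, averaged
across participants.  Participants missing any cell in any bin are dropped
entirely and reported, mirroring the missing-cell exclusions of the
original figure summaries.  Bin count defaults to 4 and is configurable;
equal-width binning was chosen because the original bin definitions are
not documented.

## Recovery harness and problem sizes

`reporting.recovery_study` repeats simulate → exclude → fit → decide and
reports per-coefficient mean posterior-mean bias, empirical 95%-HDI
coverage and reject-zero rates.  The packaged checks use 10 replications
of a 20-participant × 10-block uniform design with residual SD 60 ms —
sizes chosen so the full suite runs on a laptop in minutes.  At that size
the posterior SD of the FS/IN intercepts is ≈ 4.7 ms (the price of
estimating intercepts at the `t = b = 0` corner jointly with uncentered
drift slopes), so individual replications scatter accordingly; the
harness's aggregate bias is the stable recovery statistic.

## Known limitations

* The Gaussian likelihood ignores RT skew; a log-normal or shifted-Wald
  likelihood would change the variance structure (kept out deliberately so
  the generator and the fitted model coincide exactly).
* No per-participant slopes and no autocorrelated residuals.
* Model comparison is WAIC-only (no PSIS-LOO, no Bayes factors).
* Binary decisions only (reject / not rejected); the accept-null branch of
  the full HDI+ROPE procedure is not exposed.
* Exact third-decimal agreement with any particular published posterior
  table is not expected: prior families/scales and sampler configuration
  behind such tables are generally unknown, and agreement is only to
  within MC and prior-sensitivity tolerance.
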