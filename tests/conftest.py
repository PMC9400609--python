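import warnings

import numpy as np
import pytest

import fpseq as fq

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2025)


@pytest.fixture(scope="session")
def small_design():
    """Uniform-mix design small enough for fast fits (4 participants use it)."""
    return fq.ExperimentDesign(
        fp_short=400, fp_long=1400, n_short_per_block=12, n_long_per_block=12,
        n_catch_per_block=0, n_test_blocks=3)


@pytest.fixture(scope="session")
def small_fit(small_design):
    """A quick Model4 fit on clean simulated data, shared across tests."""
    params = fq.EffectParams.from_dict(
        {"Baseline.intercept": 320.0, "CF.intercept": -12.0,
         "FS.intercept": 15.0, "IN.intercept": -15.0},
        sigma_participant=20.0, sigma_residual=50.0, p_error=0.0,
        p_outlier=0.0, n_participants=6, seed=11)
    trials = fq.simulate_experiment(small_design, params)
    retained, _ = fq.apply_exclusions(fq.annotate(trials), has_catch=False)
    rows = fq.build_design_rows(retained)
    model = fq.build_model(fq.get_variant("Model4"), fq.PriorSpec(), rows)
    return fq.fit(model, chains=2, warmup=300, samples=400, seed=5)
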