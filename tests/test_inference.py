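import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fpseq as fq
from fpseq.inference import PosteriorFit, _slice_sample_positive


# ---------------------------------------------------------------------------
# HDI
# ---------------------------------------------------------------------------

def _hdi_bruteforce(draws, mass):
    """O(n^2) oracle: scan every pair of order statistics."""
    x = np.sort(draws)
    n = x.size
    k = math.ceil(mass * n)
    best = (math.inf, None)
    for i in range(n - k + 1):
        width = x[i + k - 1] - x[i]
        if width < best[0]:
            best = (width, (x[i], x[i + k - 1]))
    return best[1]


class TestHDI:
    def test_matches_bruteforce_scan(self, rng):
        for dist in (rng.standard_normal(1000), rng.exponential(size=1000),
                     rng.beta(2, 5, size=1000) * 10):
            for mass in (0.5, 0.9, 0.95):
                assert fq.hdi(dist, mass) == _hdi_bruteforce(dist, mass)

    def test_grid_interval_width(self):
        x = np.linspace(0, 1, 10001)
        lo, hi = fq.hdi(x, 0.95)
        assert abs((hi - lo) - 0.95) <= 1e-4  # one grid step

    def test_constant_vector(self):
        lo, hi = fq.hdi(np.full(500, 3.5))
        assert (lo, hi) == (3.5, 3.5)

    def test_large_sample_normal_endpoints(self, rng):
        lo, hi = fq.hdi(rng.standard_normal(100_000), 0.95)
        assert abs(lo + 1.96) < 0.03 and abs(hi - 1.96) < 0.03

    def test_agrees_with_arviz(self, rng):
        import arviz as az
        draws = rng.gamma(3.0, 2.0, size=5000)
        ours = fq.hdi(draws, 0.95)
        theirs = az.hdi(draws, hdi_prob=0.95)
        # conventions differ by one order statistic (ceil vs floor window)
        assert np.allclose(ours, theirs, atol=0.05)

    def test_nesting_on_unimodal_draws(self, rng):
        draws = rng.standard_normal(2000)
        lo1, hi1 = fq.hdi(draws, 0.5)
        lo2, hi2 = fq.hdi(draws, 0.95)
        assert lo2 <= lo1 and hi1 <= hi2

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fq.hdi(np.arange(50))


# ---------------------------------------------------------------------------
# ROPE + decision
# ---------------------------------------------------------------------------

class TestRopeDecision:
    @pytest.mark.parametrize("sd, hi", [(3.62, 0.362), (2.84, 0.284), (0.0, 0.0)])
    def test_rope_is_a_tenth_of_posterior_sd(self, sd, hi):
        lo_got, hi_got = fq.rope_bounds(sd)
        assert hi_got == pytest.approx(hi, abs=1e-12)
        assert lo_got == pytest.approx(-hi, abs=1e-12)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            fq.rope_bounds(-1.0)

    @pytest.mark.parametrize("hdi95, rope, expect", [
        ((13.57, 26.68), (-0.331, 0.331), "reject_zero"),
        ((0.01, 0.65), (-0.016, 0.016), "not_rejected"),
        ((-1.11, -0.18), (-0.024, 0.024), "reject_zero"),
    ])
    def test_decision_examples(self, hdi95, rope, expect):
        assert fq.decide(hdi95, rope) == expect

    @given(lo=st.floats(-50, 50), width=st.floats(0, 20),
           sd=st.floats(0.01, 10), shrink=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=300)
    def test_shrinking_rope_never_unrejects(self, lo, width, sd, shrink):
        hdi95 = (lo, lo + width)
        if fq.decide(hdi95, fq.rope_bounds(sd)) == "reject_zero":
            smaller = fq.rope_bounds(sd, multiplier=0.1 * shrink)
            assert fq.decide(hdi95, smaller) == "reject_zero"


# ---------------------------------------------------------------------------
# WAIC and comparison
# ---------------------------------------------------------------------------

def _waic_bruteforce(ll):
    """Spreadsheet-style evaluation with explicit loops."""
    n, s = ll.shape
    pointwise = []
    for i in range(n):
        lppd = math.log(sum(math.exp(v) for v in ll[i]) / s)
        mean = sum(ll[i]) / s
        var = sum((v - mean) ** 2 for v in ll[i]) / s
        pointwise.append(-2.0 * (lppd - var))
    total = sum(pointwise)
    m = total / n
    se = math.sqrt(n * sum((w - m) ** 2 for w in pointwise) / n)
    return total, pointwise, se


class TestWAIC:
    def test_toy_matrix_matches_direct_evaluation(self, rng):
        ll = rng.normal(-1.0, 0.5, size=(5, 4))
        total, pointwise, se = fq.waic(ll)
        o_total, o_pointwise, o_se = _waic_bruteforce(ll)
        assert np.isclose(total, o_total)
        assert np.allclose(pointwise, o_pointwise)
        assert np.isclose(se, o_se)

    def test_single_draw_has_zero_penalty(self):
        ll = np.array([[-1.0], [-2.0], [-0.5]])
        total, pointwise, _ = fq.waic(ll)
        assert np.isclose(total, -2 * ll.sum())

    def test_duplicated_draws_leave_waic_unchanged(self, rng):
        ll = rng.normal(-1.0, 0.5, size=(8, 6))
        base = fq.waic(ll)[0]
        dup = fq.waic(np.hstack([ll, ll]))[0]
        assert np.isclose(base, dup)

    def test_agrees_with_arviz_deviance_scale(self, rng):
        import arviz as az
        import warnings
        ll = rng.normal(-2.0, 0.3, size=(40, 400))
        idata = az.from_dict(
            log_likelihood={"y": ll.T[None, :, :]})  # (chain, draw, obs)
        ours_total, _, ours_se = fq.waic(ll)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = az.waic(idata, scale="deviance")
        assert np.isclose(ours_total, float(theirs.elpd_waic), rtol=1e-6)
        assert np.isclose(ours_se, float(theirs.se), rtol=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fq.waic(np.array([[0.0, -np.inf]]))


class TestCompare:
    def test_akaike_weights_closed_form(self):
        pw = {"A": np.full(10, 0.0), "B": np.full(10, 0.2), "C": np.full(10, 0.4)}
        waics = {k: (float(v.sum()), v, 0.0) for k, v in pw.items()}
        table = fq.compare(waics).table
        assert np.allclose(table["weight"],
                           [0.665, 0.245, 0.090], atol=5e-4)
        assert table["dwaic"].iloc[0] == 0.0

    def test_difference_interval_matches_hand_computation(self):
        pw_a = np.array([1.0, 2.0, 3.0, 4.0])
        pw_b = np.array([1.5, 2.1, 3.9, 4.5])
        waics = {"A": (pw_a.sum(), pw_a, 0.0), "B": (pw_b.sum(), pw_b, 0.0)}
        table = fq.compare(waics).table
        diff = pw_b - pw_a
        dw = diff.sum()
        dse = math.sqrt(4 * diff.var())
        row = table.loc["B"]
        assert np.isclose(row["dwaic"], dw)
        assert np.isclose(row["dse"], dse)
        assert np.isclose(row["dwaic_low"], dw - 1.96 * dse)
        assert np.isclose(row["dwaic_high"], dw + 1.96 * dse)

    def test_identical_models_share_weight(self):
        pw = np.array([1.0, 2.0, 3.0])
        waics = {"A": (6.0, pw, 0.0), "B": (6.0, pw.copy(), 0.0)}
        table = fq.compare(waics).table
        assert np.allclose(table["weight"], [0.5, 0.5])

    def test_weights_normalised_and_permutation_invariant(self, rng):
        pws = {k: rng.normal(size=20) for k in "ABC"}
        waics = {k: (float(v.sum()), v, 1.0) for k, v in pws.items()}
        t1 = fq.compare(waics).table
        t2 = fq.compare(dict(reversed(list(waics.items())))).table
        assert np.isclose(t1["weight"].sum(), 1.0)
        assert t1.sort_index().equals(t2.sort_index())

    def test_mismatched_observations_rejected(self):
        waics = {"A": (0.0, np.zeros(5), 0.0), "B": (0.0, np.zeros(6), 0.0)}
        with pytest.raises(ValueError, match="observation"):
            fq.compare(waics)


# ---------------------------------------------------------------------------
# Sampler correctness
# ---------------------------------------------------------------------------

class TestSlicekernel:
    def test_samples_half_normal_target(self):
        scale = 7.0
        rng = np.random.default_rng(1)
        x, draws = 1.0, []
        for _ in range(20000):
            x = _slice_sample_positive(
                lambda s: -s * s / (2 * scale**2), x, rng, w=3.0)
            draws.append(x)
        draws = np.asarray(draws[2000:])
        assert abs(draws.mean() - scale * math.sqrt(2 / math.pi)) < 0.15
        assert abs(np.median(draws) - scale * 0.6745) < 0.15


class TestFit:
    def test_fixed_seed_reproduces_draws(self, small_fit):
        refit = fq.fit(small_fit.model, chains=2, warmup=300, samples=400, seed=5)
        for name in small_fit.parameter_names:
            assert np.array_equal(small_fit.draws(name), refit.draws(name))

    def test_recovers_generating_intercepts(self, small_fit):
        truth = {"Baseline.intercept": 320.0, "CF.intercept": -12.0,
                 "FS.intercept": 15.0, "IN.intercept": -15.0}
        for name, value in truth.items():
            d = small_fit.draws(name)
            lo, hi = fq.hdi(d)
            margin = 2 * np.std(d)
            assert lo - margin < value < hi + margin

    def test_diagnostics_attached_and_clean(self, small_fit):
        diag = small_fit.diagnostics
        assert {"rhat", "ess_bulk"} <= set(diag.columns)
        assert (diag["rhat"] < 1.05).all()
        assert not small_fit.flagged

    def test_single_chain_rejected(self, small_fit):
        with pytest.raises(ValueError, match="chains"):
            fq.fit(small_fit.model, chains=1, warmup=10, samples=10, seed=0)

    def test_posterior_means_match_known_variance_conjugate_form(self, small_fit):
        """In the known-variance limit the whole coefficient vector (shared
        terms, participant intercepts, group mean) has an exact Normal
        posterior; with the variance parameters pinned at their posterior
        means the sampled coefficient means must land near that closed form."""
        m = small_fit.model
        p, P = len(m.terms), m.n_participants
        sig_r = float(np.mean(small_fit.draws("sigma_residual")))
        sig_p = float(np.mean(small_fit.draws("sigma_participant")))
        Z = np.zeros((m.n_obs, P))
        Z[np.arange(m.n_obs), m.participant_index] = 1.0
        q = p + P + 1
        prec = np.zeros((q, q))
        rhs = np.zeros(q)
        prec[:p, :p] = m.X.T @ m.X / sig_r**2 + np.eye(p) / m.priors.s_fixed**2
        prec[:p, p:p + P] = m.X.T @ Z / sig_r**2
        prec[p:p + P, :p] = prec[:p, p:p + P].T
        prec[p:p + P, p:p + P] = (np.diag(Z.sum(0)) / sig_r**2
                                  + np.eye(P) / sig_p**2)
        prec[p:p + P, -1] = prec[-1, p:p + P] = -1.0 / sig_p**2
        prec[-1, -1] = P / sig_p**2 + 1.0 / m.priors.s_baseline**2
        rhs[:p] = m.X.T @ m.y / sig_r**2
        rhs[p:p + P] = Z.T @ m.y / sig_r**2
        rhs[-1] = m.baseline_loc / m.priors.s_baseline**2
        mean = np.linalg.solve(prec, rhs)
        for j, t in enumerate(m.terms):
            d = small_fit.draws(t)
            assert abs(np.mean(d) - mean[j]) < 0.3 * np.std(d)
        b0 = small_fit.draws("Baseline.intercept")
        assert abs(np.mean(b0) - mean[-1]) < 0.3 * np.std(b0)

    def test_posterior_matches_emcee_on_small_dataset(self, small_fit):
        """Independent route: sample the same posterior with an affine-
        invariant ensemble sampler and compare posterior means."""
        import emcee

        m = small_fit.model
        p = len(m.terms)
        P = m.n_participants
        pidx = m.participant_index

        def logpost(v):
            theta, a, b0 = v[:p], v[p:p + P], v[p + P]
            lsp, lsr = v[p + P + 1], v[p + P + 2]
            if not (-3 < lsp < 8 and -3 < lsr < 8):
                return -np.inf
            sp, sr = math.exp(lsp), math.exp(lsr)
            resid = m.y - m.X @ theta - a[pidx]
            ll = -m.n_obs * lsr - np.sum(resid**2) / (2 * sr**2)
            lp = (-np.sum(theta**2) / (2 * m.priors.s_fixed**2)
                  - np.sum((a - b0)**2) / (2 * sp**2) - P * lsp
                  - (b0 - m.baseline_loc)**2 / (2 * m.priors.s_baseline**2)
                  - sp**2 / (2 * m.priors.s_sd**2)
                  - sr**2 / (2 * m.priors.s_residual**2)
                  + lsp + lsr)  # log-scale Jacobian
            return ll + lp

        ndim = p + P + 3
        rng = np.random.default_rng(0)
        start = np.concatenate([
            [np.mean(small_fit.draws(t)) for t in m.terms],
            small_fit.participant_intercepts.reshape(-1, P).mean(0),
            [np.mean(small_fit.draws("Baseline.intercept"))],
            [math.log(np.mean(small_fit.draws("sigma_participant")))],
            [math.log(np.mean(small_fit.draws("sigma_residual")))]])
        walkers = 2 * ndim + 2
        p0 = start + 0.01 * rng.standard_normal((walkers, ndim))
        sampler = emcee.EnsembleSampler(walkers, ndim, logpost)
        sampler.run_mcmc(p0, 4000, progress=False)
        chain = sampler.get_chain(discard=2000, flat=True)
        for j, t in enumerate(m.terms):
            ours = small_fit.draws(t)
            sd = np.std(ours)
            assert abs(np.mean(ours) - chain[:, j].mean()) < 0.35 * sd


class TestPosteriorProbability:
    def _fake_fit(self, fs, in_):
        """Minimal PosteriorFit stub carrying given draws."""
        model = type("M", (), {"spec": type("S", (), {"name": "stub"})(),
                               "terms": ("FS.intercept", "IN.intercept")})()
        return PosteriorFit(
            model=model,
            coef={"FS.intercept": fs, "IN.intercept": in_},
            baseline_mean=np.zeros_like(fs),
            participant_intercepts=np.zeros(fs.shape + (2,)),
            sigma_participant=np.ones_like(fs),
            sigma_residual=np.ones_like(fs), seed=0)

    def test_symmetric_draws_give_half(self, rng):
        x = rng.standard_normal((2, 4000))
        f = self._fake_fit(x, -x)
        assert abs(fq.posterior_probability(f, {"FS.intercept": 1.0}) - 0.5) < 0.03

    def test_long_fp_sequence_effect_expression(self, rng):
        fs = rng.normal(14.0, 3.0, size=(2, 4000))
        in_ = rng.normal(-14.0, 3.0, size=(2, 4000))
        f = self._fake_fit(fs, in_)
        prob = fq.posterior_probability(
            f, {"FS.intercept": 1.0, "IN.intercept": 1.0}, ">")
        assert 0.35 < prob < 0.65  # F + A centred on zero: sign-ambiguous

    def test_unknown_parameter_rejected(self, rng):
        f = self._fake_fit(rng.standard_normal((2, 200)),
                           rng.standard_normal((2, 200)))
        with pytest.raises(KeyError):
            fq.posterior_probability(f, {"CF.intercept": 1.0})
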