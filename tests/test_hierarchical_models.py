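"""Model arithmetic, builders, the HMC fitting contract, and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fairsent import _engine
from fairsent.hierarchical_models import (
    MCMCConfig,
    PosteriorSamples,
    PriorConfig,
    accuracy_prob,
    build_accuracy_model,
    build_rt_model,
    check_convergence,
    fit_model,
    rt_location,
)
from fairsent.synthetic_experiment import SimConfig, simulate_trials
from fairsent.trial_data import COLUMNS, filter_positive_responses, standardize_rt


class TestRtLocation:
    def test_all_zero_coefficients(self):
        fixed = {"beta0": 0.0, "beta_gender": 0.0}
        assert rt_location(fixed, 0.0, 0.0, gender=1) == 0.0

    def test_hand_summed_linear_predictor(self):
        fixed = {"beta0": 0.10, "beta_gender": -0.22}
        assert rt_location(fixed, -0.05, 0.05, gender=1) == pytest.approx(-0.12)

    def test_feminine_coding_ignores_gender_coefficient(self):
        a = rt_location({"beta0": 0.3, "beta_gender": -0.9}, 0.1, -0.2, gender=0)
        b = rt_location({"beta0": 0.3, "beta_gender": 7.0}, 0.1, -0.2, gender=0)
        assert a == b

    def test_condition_terms(self):
        fixed = {
            "beta0": 0.1,
            "beta_gender": -0.2,
            "beta_condition": -0.17,
            "beta_gender_condition": 0.26,
        }
        assert rt_location(fixed, 0, 0, gender=1, condition=1) == pytest.approx(-0.01)

    def test_missing_coefficient_errors(self):
        with pytest.raises(KeyError, match="beta_gender"):
            rt_location({"beta0": 0.0}, 0, 0, gender=1)


class TestAccuracyProb:
    def test_chance_anchoring_at_zero_predictor(self):
        fixed = {"beta0": 0.0, "beta_gender": 0.0}
        assert accuracy_prob(fixed, 0, 0, gender=0, p_miss=0.0) == pytest.approx(0.75)

    def test_lower_asymptote_is_chance(self):
        fixed = {"beta0": -40.0, "beta_gender": 0.0}
        assert accuracy_prob(fixed, 0, 0, gender=0, p_miss=0.3) == pytest.approx(0.5)

    def test_worked_value(self):
        fixed = {"beta0": 1.49, "beta_gender": 0.0}
        assert accuracy_prob(fixed, 0, 0, gender=0, p_miss=0.06) == pytest.approx(
            0.8590744, abs=1e-6
        )

    def test_pmiss_domain(self):
        fixed = {"beta0": 0.0, "beta_gender": 0.0}
        for bad in (-0.01, 0.5, 0.7):
            with pytest.raises(ValueError, match="p_miss"):
                accuracy_prob(fixed, 0, 0, gender=0, p_miss=bad)

    @given(
        eta=st.floats(-8, 8),
        delta=st.floats(0.01, 2.0),
        pm=st.floats(0, 0.49),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_predictor(self, eta, delta, pm):
        f1 = {"beta0": eta, "beta_gender": 0.0}
        f2 = {"beta0": eta + delta, "beta_gender": 0.0}
        assert accuracy_prob(f2, 0, 0, 0, p_miss=pm) > accuracy_prob(f1, 0, 0, 0, p_miss=pm)

    @given(eta=st.floats(-8, 8), pm=st.floats(0, 0.44))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_lapse_rate(self, eta, pm):
        f = {"beta0": eta, "beta_gender": 0.0}
        assert accuracy_prob(f, 0, 0, 0, p_miss=pm + 0.05) < accuracy_prob(f, 0, 0, 0, p_miss=pm)


class TestModelBuilders:
    def test_experiment1_effects(self, exp1_small):
        std = standardize_rt(filter_positive_responses(exp1_small))
        spec = build_rt_model(std, 1)
        assert spec.fixed_effects == ["beta0", "beta_gender"]
        aspec = build_accuracy_model(exp1_small, 1)
        assert aspec.fixed_effects == ["beta0", "beta_gender"]
        assert aspec.likelihood == "lapse_logistic_acc"

    def test_experiment2_adds_condition_terms(self):
        cfg = SimConfig(experiment=2, n_participants=3, n_items=4, seed=0)
        t = simulate_trials(cfg)
        std = standardize_rt(filter_positive_responses(t))
        spec = build_rt_model(std, 2)
        assert spec.fixed_effects == [
            "beta0",
            "beta_gender",
            "beta_condition",
            "beta_gender_condition",
        ]

    def test_unfiltered_table_rejected(self, exp1_small):
        with pytest.raises(ValueError, match="rt_z"):
            build_rt_model(exp1_small, 1)
        withz = exp1_small.assign(rt_z=0.0)
        with pytest.raises(ValueError, match="positive"):
            build_rt_model(withz, 1)

    def test_lapse_prior_mean_is_one_third(self):
        prior = PriorConfig()
        assert prior.pmiss_alpha / (prior.pmiss_alpha + prior.pmiss_beta) == pytest.approx(1 / 3)


def _random_glmm_point(rng, kind, k):
    n, n_p, n_i = 30, 4, 3
    y = (
        rng.normal(size=n)
        if kind == _engine.GAUSSIAN_RT
        else (rng.random(n) < 0.7).astype(float)
    )
    g = rng.integers(0, 2, n).astype(float)
    c = rng.integers(0, 2, n).astype(float)
    pidx = rng.integers(0, n_p, n)
    iidx = rng.integers(0, n_i, n)
    x = rng.normal(size=k + 3 + n_p + n_i) * 0.8
    return y, g, c, pidx, iidx, n_p, n_i, x


def _scipy_log_posterior(kind, x, y, g, c, pidx, iidx, n_p, n_i, k, scales, prior):
    """Fully normalized log posterior via scipy density calls — an
    independent re-implementation sharing no arithmetic with the engine."""
    fixed = x[:k]
    sp, si = np.exp(x[k]), np.exp(x[k + 1])
    zp = x[k + 3 : k + 3 + n_p]
    zi = x[k + 3 + n_p :]
    X = np.column_stack([np.ones_like(g), g, c, g * c][:k])
    eta = X @ fixed + sp * zp[pidx] + si * zi[iidx]
    if kind == _engine.GAUSSIAN_RT:
        sr = np.exp(x[k + 2])
        lp = stats.norm.logpdf(y, loc=eta, scale=sr).sum()
        # Gamma prior on sigma_resid with log-transform Jacobian
        lp += stats.gamma.logpdf(sr, prior[0], scale=1 / prior[1]) + x[k + 2]
    else:
        pm = stats.logistic.cdf(x[k + 2])
        P = 0.5 + (0.5 - pm) * stats.logistic.cdf(eta)
        lp = stats.bernoulli.logpmf(y.astype(int), P).sum()
        # Beta prior on p_miss with logit-transform Jacobian
        lp += stats.beta.logpdf(pm, prior[2], prior[3]) + np.log(pm * (1 - pm))
    lp += stats.norm.logpdf(zp).sum() + stats.norm.logpdf(zi).sum()
    lp += stats.norm.logpdf(fixed, scale=scales).sum()
    for ls, s in ((x[k], sp), (x[k + 1], si)):
        lp += stats.gamma.logpdf(s, prior[0], scale=1 / prior[1]) + ls
    return lp


class TestPotential:
    @pytest.mark.parametrize("kind", [_engine.GAUSSIAN_RT, _engine.LAPSE_LOGISTIC])
    @pytest.mark.parametrize("k", [2, 4])
    def test_matches_independent_scipy_arithmetic(self, kind, k):
        """Log-posterior differences between random parameter points agree
        with direct density arithmetic to 1e-10 relative error (differences
        cancel the normalizing constants the sampler legitimately drops)."""
        rng = np.random.default_rng(17)
        prior = np.array([2.0, 0.1, 5.0, 10.0])
        scales = np.ones(k)
        for _ in range(25):
            y, g, c, pidx, iidx, n_p, n_i, x1 = _random_glmm_point(rng, kind, k)
            x2 = x1 + rng.normal(size=x1.size) * 0.5
            buf = np.zeros_like(x1)
            dU = _engine.glmm_potential(
                kind, x2, y, g, c, pidx, iidx, n_p, n_i, k, scales, prior, buf
            ) - _engine.glmm_potential(
                kind, x1, y, g, c, pidx, iidx, n_p, n_i, k, scales, prior, buf
            )
            dref = _scipy_log_posterior(
                kind, x1, y, g, c, pidx, iidx, n_p, n_i, k, scales, prior
            ) - _scipy_log_posterior(
                kind, x2, y, g, c, pidx, iidx, n_p, n_i, k, scales, prior
            )
            assert abs(dU - dref) <= 1e-10 * max(1.0, abs(dref))

    @pytest.mark.parametrize("kind", [_engine.GAUSSIAN_RT, _engine.LAPSE_LOGISTIC])
    def test_gradient_matches_finite_differences(self, kind):
        rng = np.random.default_rng(3)
        k = 4
        prior = np.array([2.0, 0.1, 5.0, 10.0])
        scales = np.ones(k)
        y, g, c, pidx, iidx, n_p, n_i, x = _random_glmm_point(rng, kind, k)
        grad = np.zeros_like(x)
        _engine.glmm_potential(kind, x, y, g, c, pidx, iidx, n_p, n_i, k, scales, prior, grad)
        h = 1e-6
        for j in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            buf = np.zeros_like(x)
            up = _engine.glmm_potential(
                kind, xp, y, g, c, pidx, iidx, n_p, n_i, k, scales, prior, buf
            )
            um = _engine.glmm_potential(
                kind, xm, y, g, c, pidx, iidx, n_p, n_i, k, scales, prior, buf
            )
            fd = (up - um) / (2 * h)
            assert abs(fd - grad[j]) < 1e-4 * max(1.0, abs(fd))


def _empty_trials():
    df = pd.DataFrame(columns=COLUMNS + ["rt_z"])
    df["correct"] = df["correct"].astype("boolean")
    for col in ("rt_ms", "rt_z"):
        df[col] = df[col].astype(float)
    return df


class TestFitModel:
    def test_prior_only_fit_recovers_standard_normal(self):
        """With no data the posterior for beta_gender is its N(0,1) prior."""
        spec = build_rt_model(_empty_trials(), 1)
        samples, _ = fit_model(spec, _empty_trials(), MCMCConfig.fast(seed=8))
        bg = samples.flat("beta_gender")
        assert abs(bg.mean()) < 0.1
        assert abs(bg.std() - 1.0) < 0.1

    def test_same_seed_reproduces_draws_exactly(self, exp1_small):
        std = standardize_rt(filter_positive_responses(exp1_small))
        spec = build_rt_model(std, 1)
        mcmc = MCMCConfig.reduced(seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, _ = fit_model(spec, std, mcmc)
            b, _ = fit_model(spec, std, mcmc)
        np.testing.assert_array_equal(a.draws["beta_gender"], b.draws["beta_gender"])

    def test_posterior_mean_invariant_to_relabeling(self, exp1_small):
        std = standardize_rt(filter_positive_responses(exp1_small))
        relabeled = std.copy()
        pmap = {p: f"Q{99 - int(p[1:]):03d}" for p in std["participant_id"].unique()}
        imap = {w: f"V{99 - int(w[1:]):03d}" for w in std["item_id"].unique()}
        relabeled["participant_id"] = relabeled["participant_id"].map(pmap)
        relabeled["item_id"] = relabeled["item_id"].map(imap)
        spec = build_rt_model(std, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, _ = fit_model(spec, std, MCMCConfig.fast(seed=2))
            b, _ = fit_model(spec, relabeled, MCMCConfig.fast(seed=2))
        assert abs(a.flat("beta_gender").mean() - b.flat("beta_gender").mean()) < 0.05

    def test_nonconvergence_is_flagged_not_silent(self, exp1_small):
        std = standardize_rt(filter_positive_responses(exp1_small))
        spec = build_rt_model(std, 1)
        short = MCMCConfig(n_chains=2, n_iter_per_chain=60, n_burnin=30, n_retained=30, seed=1)
        with pytest.warns(UserWarning, match="convergence"):
            _, diag = fit_model(spec, std, short)
        assert not diag.passed


class TestCheckConvergence:
    @staticmethod
    def _samples(arrs, n_div=0):
        return PosteriorSamples(draws={"theta": np.asarray(arrs)}, n_divergent=n_div)

    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        s = self._samples(rng.standard_normal((4, 1000)))
        d = check_convergence(s)
        assert d.rhat["theta"] < 1.01
        assert d.effective_sample_size["theta"] > 400
        assert d.passed

    def test_offset_chain_fails(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((4, 1000))
        arr[0] += 10.0
        d = check_convergence(self._samples(arr))
        assert d.rhat["theta"] > 1.01
        assert not d.passed

    def test_divergences_fail_even_when_mixed(self):
        rng = np.random.default_rng(0)
        d = check_convergence(self._samples(rng.standard_normal((4, 1000)), n_div=3))
        assert not d.passed

    def test_ar1_chains_have_small_ess(self):
        rho, n = 0.9, 1000
        rng = np.random.default_rng(1)
        chains = np.empty((4, n))
        for ch in range(4):
            x = 0.0
            for t in range(n):
                x = rho * x + rng.standard_normal() * np.sqrt(1 - rho**2)
                chains[ch, t] = x
        d = check_convergence(self._samples(chains))
        # AR(1) theory: ESS ~ N (1-rho)/(1+rho) ~ 210 of 4000
        assert d.effective_sample_size["theta"] < 0.25 * 4 * n

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            check_convergence(self._samples(np.zeros((1, 100))))
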