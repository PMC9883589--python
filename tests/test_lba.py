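"""Closed-form race quantities, censored likelihood, and the Bayesian fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from gonogo.lba import (IneligibleSessionError, LBAParams, default_priors,
                        defective_go_density, derived_metrics, fit_lba,
                        lba_eligible, prob_go_by_deadline, session_loglik,
                        single_cdf, single_pdf, trial_loglik)
from conftest import make_session

BASE = dict(t0=0.25, A=0.35, B_go=0.45, B_nogo=0.60, v_target_go=2.8,
            v_target_nogo=0.6, v_foil_go=0.3, v_foil_nogo=2.6)

FAST_MCMC = {"n_chains": 16, "n_steps": 300, "burn_in": 100, "seed": 0}


class TestSingleAccumulator:
    def test_degenerate_limit_is_a_step(self):
        # A=0, s->0: crossing at exactly t = b/v = 0.5
        assert single_cdf(0.49, 0.0, 1.0, 2.0, 1e-9) == pytest.approx(0.0)
        assert single_cdf(0.51, 0.0, 1.0, 2.0, 1e-9) == pytest.approx(1.0)

    def test_zero_A_equals_analytic_limit(self):
        t, b, v, s = 0.6, 1.0, 2.0, 1.0
        assert single_cdf(t, 0.0, b, v, s) == pytest.approx(
            stats.norm.cdf((t * v - b) / (t * s)))

    def test_cdf_matches_monte_carlo(self):
        A, b, v, s, t = 0.5, 1.0, 2.0, 1.0, 0.6
        rng = np.random.default_rng(1)
        n = 10**6
        starts = rng.uniform(0, A, n)
        slopes = rng.normal(v, s, n)
        with np.errstate(divide="ignore"):
            crossed = (slopes > 0) & ((b - starts) / slopes <= t)
        exact = float(single_cdf(t, A, b, v, s))
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(crossed.mean() - exact) < 3 * se

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(A=st.floats(0.0, 1.5), B=st.floats(0.05, 1.5),
           v=st.floats(-1.0, 4.0), s=st.floats(0.3, 2.0))
    def test_cdf_monotone_and_pdf_nonnegative(self, A, B, v, s):
        b = A + B
        grid = np.linspace(0.05, 2.5, 40)
        cdf = single_cdf(grid, A, b, v, s)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert np.all(cdf >= 0) and np.all(cdf <= 1)
        assert np.all(single_pdf(grid, A, b, v, s) >= 0)

    def test_pdf_is_derivative_of_cdf(self):
        rng = np.random.default_rng(2)
        h = 1e-5
        for _ in range(100):
            A = rng.uniform(0.05, 1.2)
            b = A + rng.uniform(0.1, 1.2)
            v = rng.uniform(-0.5, 3.5)
            s = rng.uniform(0.4, 1.8)
            t = rng.uniform(0.1, 2.0)
            num = (single_cdf(t + h, A, b, v, s)
                   - single_cdf(t - h, A, b, v, s)) / (2 * h)
            pdf = float(single_pdf(t, A, b, v, s))
            assert pdf == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_pdf_integrates_to_limiting_cdf(self):
        # mass can be < 1: negative slopes never cross
        A, b, v, s = 0.4, 1.0, 0.8, 1.0
        total, _ = integrate.quad(lambda t: single_pdf(t, A, b, v, s),
                                  1e-9, np.inf, limit=400)
        limit = float(single_cdf(1e7, A, b, v, s))
        assert total == pytest.approx(limit, abs=1e-4)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            single_cdf(-0.1, 0.3, 1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            single_cdf(0.5, 1.0, 0.5, 2.0, 1.0)  # b <= A
        with pytest.raises(ValueError):
            single_pdf(0.5, 0.3, 1.0, 2.0, 0.0)


class TestDefectiveDensity:
    def test_symmetric_race_splits_crossing_mass_evenly(self):
        p = LBAParams(t0=0.2, A=0.3, B_go=0.6, B_nogo=0.6,
                      v_target_go=1.5, v_target_nogo=1.5,
                      v_foil_go=1.5, v_foil_nogo=1.5)
        go_mass, _ = integrate.quad(
            lambda t: defective_go_density(t, "target", p), p.t0, np.inf,
            limit=400)
        # both accumulators cross eventually unless their slope is negative
        p_neither = stats.norm.cdf(-1.5) ** 2
        assert go_mass == pytest.approx((1 - p_neither) / 2, abs=1e-3)

    def test_dominated_race_reduces_to_marginal_pdf(self):
        p = LBAParams(t0=0.2, A=0.3, B_go=0.6, B_nogo=0.6,
                      v_target_go=2.0, v_target_nogo=-30.0,
                      v_foil_go=0.5, v_foil_nogo=2.0)
        t = np.linspace(0.25, 1.4, 25)
        dens = defective_go_density(t, "target", p)
        marginal = single_pdf(t - p.t0, p.A, p.b_go, 2.0, p.s)
        assert np.allclose(dens, marginal, rtol=1e-6)

    def test_zero_before_nondecision_time(self):
        p = LBAParams(**BASE)
        assert defective_go_density(0.1, "target", p) == 0.0

    def test_integral_matches_simulated_win_rate(self):
        p = LBAParams(**BASE)
        rng = np.random.default_rng(3)
        n = 10**5
        sg = rng.uniform(0, p.A, n)
        sn = rng.uniform(0, p.A, n)
        dg = rng.normal(p.v_target_go, p.s, n)
        dn = rng.normal(p.v_target_nogo, p.s, n)
        with np.errstate(divide="ignore"):
            tg = np.where(dg > 0, (p.b_go - sg) / dg, np.inf)
            tn = np.where(dn > 0, (p.b_nogo - sn) / dn, np.inf)
        deadline = 1.0
        emp = np.mean((tg < tn) & (p.t0 + tg <= deadline))
        exact = prob_go_by_deadline("target", p, deadline)
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(emp - exact) < 3 * se

    def test_no_response_mass_decomposes(self):
        # 1 - P(Go by T) = P(No-go first, by T) + P(neither crossed by T)
        p = LBAParams(**BASE)
        deadline = 1.0
        tau = deadline - p.t0
        swapped = LBAParams(t0=p.t0, A=p.A, B_go=p.B_nogo, B_nogo=p.B_go,
                            v_target_go=p.v_target_nogo,
                            v_target_nogo=p.v_target_go,
                            v_foil_go=p.v_foil_nogo, v_foil_nogo=p.v_foil_go)
        for cls in ("target", "foil"):
            p_go = prob_go_by_deadline(cls, p, deadline)
            p_nogo = prob_go_by_deadline(cls, swapped, deadline)
            v_go, v_nogo = p.drifts(cls)
            p_neither = float(
                (1 - single_cdf(tau, p.A, p.b_go, v_go, p.s))
                * (1 - single_cdf(tau, p.A, p.b_nogo, v_nogo, p.s)))
            assert 1 - p_go == pytest.approx(p_nogo + p_neither, abs=1e-4)

    def test_hopeless_drifts_give_zero_probability(self):
        p = LBAParams(t0=0.2, A=0.3, B_go=0.6, B_nogo=0.6,
                      v_target_go=-20.0, v_target_nogo=-20.0,
                      v_foil_go=-20.0, v_foil_nogo=-20.0)
        assert prob_go_by_deadline("target", p, 1.0) == pytest.approx(0.0, abs=1e-9)
        assert prob_go_by_deadline("target", p, 0.1) == 0.0  # before t0


class TestLikelihood:
    def test_session_equals_sum_of_trials(self, filtered_session):
        p = LBAParams(**BASE)
        sub = filtered_session.head(40)
        total = sum(trial_loglik(row, p) for _, row in sub.iterrows())
        assert session_loglik(sub, p) == pytest.approx(total, rel=1e-9)

    def test_empty_session_is_zero(self, filtered_session):
        assert session_loglik(filtered_session.iloc[0:0], LBAParams(**BASE)) == 0.0

    def test_impossible_rt_is_minus_inf(self):
        p = LBAParams(**BASE)
        trial = pd.DataFrame({"stim_class": ["target"], "responded": [True],
                              "rt": [0.1]})  # below t0
        with pytest.warns(UserWarning, match="admissible"):
            assert trial_loglik(trial, p) == -np.inf

    def test_certain_go_makes_nonresponse_impossible(self):
        p = LBAParams(t0=0.2, A=0.0, B_go=0.5, B_nogo=0.5,
                      v_target_go=50.0, v_target_nogo=-50.0,
                      v_foil_go=50.0, v_foil_nogo=-50.0, s=1e-6)
        trial = pd.DataFrame({"stim_class": ["target"], "responded": [False],
                              "rt": [np.nan]})
        assert session_loglik(trial, p) < -100

    def test_true_parameters_dominate_perturbed(self, base_params):
        from gonogo.behavior import filter_rts
        from gonogo.synth import generate_schedule, simulate_session
        wins = 0
        for k in range(10):
            tr = simulate_session(generate_schedule(k), base_params,
                                  rng_seed=500 + k)
            f, _, _ = filter_rts(tr)
            ll_true = session_loglik(f, base_params)
            perturbed = LBAParams(**{**BASE, "v_target_go": BASE["v_target_go"] * 1.5,
                                     "v_foil_nogo": BASE["v_foil_nogo"] * 0.5})
            wins += ll_true > session_loglik(f, perturbed)
        assert wins == 10

    def test_invariant_to_trial_order(self, filtered_session):
        p = LBAParams(**BASE)
        shuffled = filtered_session.sample(frac=1, random_state=1)
        assert session_loglik(shuffled, p) == session_loglik(filtered_session, p)


class TestDerivedMetrics:
    def test_formulas(self):
        p = LBAParams(t0=0.2, A=0.3, B_go=0.36, B_nogo=0.50,
                      v_target_go=2.0, v_target_nogo=2.0,
                      v_foil_go=0.5, v_foil_nogo=2.5)
        d = derived_metrics(p)
        assert d.response_bias_go == pytest.approx(14.0)
        assert d.de_targets == pytest.approx(0.0)
        assert d.de_foils == pytest.approx(2.0)

    def test_equal_boundaries_mean_no_bias(self):
        p = LBAParams(**{**BASE, "B_go": 0.5, "B_nogo": 0.5})
        assert derived_metrics(p).response_bias_go == 0.0


class TestEligibility:
    @pytest.mark.parametrize("n_fa,expected", [(0, False), (1, False),
                                               (2, True), (5, True)])
    def test_two_false_alarm_rule(self, n_fa, expected):
        df = make_session(identity_responses=n_fa)
        assert lba_eligible(df) is expected

    def test_dropped_responses_do_not_count(self):
        df = make_session(identity_responses=2, rt=0.5)
        fa_rows = df.index[df["responded"] & (df["stim_class"] != "target")]
        df.loc[fa_rows, "rt"] = 1.5  # both FAs will be filtered out
        from gonogo.behavior import filter_rts
        filtered, _, _ = filter_rts(df)
        assert not lba_eligible(filtered)


class TestFit:
    def test_prior_only_medians_match_truncnorm(self, filtered_session):
        prior = default_priors()
        summary = fit_lba(filtered_session, prior_only=True,
                          mcmc={"n_chains": 32, "n_steps": 1500,
                                "burn_in": 500, "seed": 1})
        for i, name in enumerate(summary.medians):
            a = (prior.low[i] - prior.loc[i]) / prior.scale[i]
            b = (prior.high[i] - prior.loc[i]) / prior.scale[i]
            expected = stats.truncnorm.median(a, b, loc=prior.loc[i],
                                              scale=prior.scale[i])
            assert summary.medians[name] == pytest.approx(expected, abs=0.12)

    def test_same_seed_reproduces_fit_exactly(self, filtered_session):
        s1 = fit_lba(filtered_session, mcmc=FAST_MCMC)
        s2 = fit_lba(filtered_session, mcmc=FAST_MCMC)
        assert s1.medians == s2.medians
        assert s1.rhat == s2.rhat

    def test_fit_invariant_to_trial_order(self, filtered_session):
        shuffled = filtered_session.sample(frac=1, random_state=2)
        s1 = fit_lba(filtered_session, mcmc=FAST_MCMC)
        s2 = fit_lba(shuffled, mcmc=FAST_MCMC)
        assert s1.medians == s2.medians

    def test_ineligible_session_rejected(self):
        df = make_session(identity_responses=1)
        with pytest.raises(IneligibleSessionError):
            fit_lba(df, mcmc=FAST_MCMC)

    def test_empty_session_rejected(self, filtered_session):
        with pytest.raises(ValueError, match="no retained"):
            fit_lba(filtered_session.iloc[0:0], mcmc=FAST_MCMC)

    def test_point_estimates_satisfy_invariants(self, long_session):
        summary = fit_lba(long_session, mcmc={"n_chains": 24, "n_steps": 600,
                                              "burn_in": 300, "seed": 3})
        assert summary.n_samples == 24 * 300
        assert len(summary.medians) == 8
        assert all(np.isfinite(v) for v in summary.rhat.values())
        if summary.point_estimates is not None:
            p = summary.point_estimates
            assert p.t0 >= 0 and p.A >= 0 and p.B_go > 0 and p.B_nogo > 0
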