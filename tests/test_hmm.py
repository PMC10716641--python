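import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import enumerate_loglik, toy_hmm_params, toy_sequence
from fincee import hmm
from fincee.hmm import (HMMSpec, emission_logdensity, fit_hmm, forward_loglik,
                        local_decode, mixture_loglik, n_parameters,
                        n_parameters_breakdown, tpm_from_logits, wald_ci)


class TestTpmFromLogits:
    def test_zero_logits_uniform_row(self):
        row = tpm_from_logits(np.zeros(2), np.zeros(2), 0.0)
        assert np.allclose(row, 1 / 3)

    def test_closed_form_softmax(self):
        row = tpm_from_logits(np.log([2.0, 3.0]), np.zeros(2), 0.0)
        assert np.allclose(row, [1 / 6, 2 / 6, 3 / 6])

    def test_zero_covariate_ignores_beta(self):
        eta = np.array([0.3, -0.7])
        a = tpm_from_logits(eta, np.array([5.0, -5.0]), 0.0)
        b = tpm_from_logits(eta, np.zeros(2), 0.0)
        assert np.allclose(a, b)

    def test_transition_probability_monotone_in_covariate(self):
        # positive beta on one destination makes that probability increase
        eta = np.array([-1.0, -2.0])
        beta = np.array([1.5, 0.0])
        probs = [tpm_from_logits(eta, beta, x, diag_index=0)[1]
                 for x in np.linspace(-2, 2, 9)]
        assert np.all(np.diff(probs) > 0)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            tpm_from_logits(np.array([1.0, 2.0]), np.array([1e3, 0.0]), 1e3)


class TestEmissionDensity:
    STATE = {"time_shape": 5.0, "time_rate": 0.02, "depth_shape": 4.0,
             "depth_rate": 0.05, "lunge_rate": 2.0, "speed_shape": 5.0,
             "speed_rate": 3.0, "mu": 0.5, "kappa": 1.3}
    REC = {"dive_time_s": 240.0, "max_depth_m": 80.0, "lunges": 3,
           "speed_ms": 1.7, "turn_angle_rad": -0.4}

    def test_matches_term_by_term_hand_formula(self):
        from scipy.special import gammaln, ive
        s, r = self.STATE, self.REC
        expect = 0.0
        for y, a, b in ((r["dive_time_s"], s["time_shape"], s["time_rate"]),
                        (r["max_depth_m"], s["depth_shape"], s["depth_rate"]),
                        (r["speed_ms"], s["speed_shape"], s["speed_rate"])):
            expect += a * np.log(b) - gammaln(a) + (a - 1) * np.log(y) - b * y
        expect += (r["lunges"] * np.log(s["lunge_rate"]) - s["lunge_rate"]
                   - gammaln(r["lunges"] + 1))
        expect += (s["kappa"] * np.cos(r["turn_angle_rad"] - s["mu"])
                   - np.log(2 * np.pi)
                   - (np.log(ive(0, s["kappa"])) + s["kappa"]))
        assert emission_logdensity(r, s) == pytest.approx(expect, abs=1e-12)

    def test_matches_scipy_stream_densities(self):
        from scipy import stats as sps
        s, r = self.STATE, self.REC
        expect = (sps.gamma.logpdf(r["dive_time_s"], s["time_shape"],
                                   scale=1 / s["time_rate"])
                  + sps.gamma.logpdf(r["max_depth_m"], s["depth_shape"],
                                     scale=1 / s["depth_rate"])
                  + sps.poisson.logpmf(r["lunges"], s["lunge_rate"])
                  + sps.gamma.logpdf(r["speed_ms"], s["speed_shape"],
                                     scale=1 / s["speed_rate"])
                  + sps.vonmises.logpdf(r["turn_angle_rad"], s["kappa"],
                                        loc=s["mu"]))
        assert emission_logdensity(r, s) == pytest.approx(expect, abs=1e-10)

    def test_zero_kappa_uniform_circular(self):
        s = dict(self.STATE, kappa=0.0)
        base = emission_logdensity(self.REC, s)
        rot = emission_logdensity(dict(self.REC, turn_angle_rad=2.9), s)
        assert base == pytest.approx(rot, abs=1e-12)

    def test_nonpositive_gamma_stream_minus_inf(self):
        with pytest.warns(UserWarning):
            v = emission_logdensity(dict(self.REC, max_depth_m=0.0), self.STATE)
        assert v == -np.inf


class TestForwardLoglik:
    def test_single_observation_is_mixture_over_initials(self):
        p = toy_hmm_params(2, 1)
        seq = toy_sequence(1, seed=3)
        direct = np.logaddexp(
            np.log(p.delta[0, 0]) + emission_logdensity(
                seq.iloc[0], _state_dict(p, 0)),
            np.log(p.delta[0, 1]) + emission_logdensity(
                seq.iloc[0], _state_dict(p, 1)))
        assert forward_loglik(seq, p, 1) == pytest.approx(direct, abs=1e-10)

    def test_single_state_chain_sums_densities(self):
        p = toy_hmm_params(1, 1)
        seq = toy_sequence(7, seed=5)
        expect = sum(emission_logdensity(seq.iloc[t], _state_dict(p, 0))
                     for t in range(7))
        assert forward_loglik(seq, p, 1) == pytest.approx(expect, abs=1e-9)

    def test_matches_enumeration_toy_case(self):
        p = toy_hmm_params(2, 1, beta=0.4, seed=2)
        seq = toy_sequence(3, seed=8, with_cov=True)
        assert forward_loglik(seq, p, 1) == pytest.approx(
            enumerate_loglik(seq, p, 0), abs=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(T=st.integers(1, 6), N=st.integers(1, 3),
           seed=st.integers(0, 50), beta=st.floats(-1, 1))
    def test_forward_equals_path_enumeration(self, T, N, seed, beta):
        p = toy_hmm_params(N, 1, beta=beta, seed=seed)
        seq = toy_sequence(T, seed=seed, with_cov=True)
        assert forward_loglik(seq, p, 1) == pytest.approx(
            enumerate_loglik(seq, p, 0), abs=1e-10)


class TestMixtureLoglik:
    def test_single_context_degenerates_to_forward(self):
        p = toy_hmm_params(2, 1)
        seq = toy_sequence(10, seed=1)
        assert mixture_loglik(seq, p) == pytest.approx(
            forward_loglik(seq, p, 1), abs=1e-10)

    def test_identical_contexts_independent_of_pi(self):
        p = toy_hmm_params(2, 2, seed=4)
        p.eta[1] = p.eta[0]
        p.delta[1] = p.delta[0]
        seq = toy_sequence(12, seed=4)
        p.pi = np.array([0.5, 0.5])
        a = mixture_loglik(seq, p)
        p.pi = np.array([0.9, 0.1])
        b = mixture_loglik(seq, p)
        assert a == pytest.approx(b, abs=1e-10)

    def test_two_whale_two_context_hand_arithmetic(self):
        p = toy_hmm_params(2, 2, seed=6)
        w0 = toy_sequence(3, seed=10)
        w1 = toy_sequence(4, seed=11).assign(whale_id="w1")
        data = pd.concat([w0, w1], ignore_index=True)
        expect = 0.0
        for seq in (w0, w1.assign(whale_id="w0")):
            lls = [enumerate_loglik(seq, p, k) for k in range(2)]
            expect += np.logaddexp(np.log(p.pi[0]) + lls[0],
                                   np.log(p.pi[1]) + lls[1])
        assert mixture_loglik(data, p) == pytest.approx(expect, abs=1e-10)

    def test_invariance_under_context_and_state_relabelling(self):
        p = toy_hmm_params(3, 2, beta=0.3, seed=9)
        seq = toy_sequence(8, seed=12, with_cov=True)
        base = mixture_loglik(seq, p)
        perm, kperm = [2, 0, 1], [1, 0]
        from dataclasses import replace
        q = replace(
            p,
            time_shape=p.time_shape[perm], time_rate=p.time_rate[perm],
            depth_shape=p.depth_shape[perm], depth_rate=p.depth_rate[perm],
            lunge_rate=p.lunge_rate[perm],
            speed_shape=p.speed_shape[perm], speed_rate=p.speed_rate[perm],
            mu=p.mu[perm], kappa=p.kappa[perm],
            eta=p.eta[np.ix_(kperm, perm, perm)],
            beta=p.beta[np.ix_([0], kperm, perm, perm)],
            delta=p.delta[np.ix_(kperm, perm)], pi=p.pi[kperm])
        assert mixture_loglik(seq, q) == pytest.approx(base, abs=1e-9)


class TestNParameters:
    def test_shared_continuous_covariate_has_six_coefficients(self):
        for k in (1, 3, 5):
            spec = HMMSpec(n_states=3, n_contexts=k, covariate="max_rl",
                           covariate_sharing="shared")
            assert n_parameters_breakdown(spec)["covariate"] == 6

    def test_baseline_three_state_count(self):
        assert n_parameters(HMMSpec(3, 1, "none")) == 35  # 27 + 6 + 2

    def test_five_context_shared_covariate_count(self):
        assert n_parameters(HMMSpec(3, 5, "max_rl")) == 77  # 27+30+10+4+6

    def test_per_context_and_phase_scaling(self):
        assert n_parameters_breakdown(
            HMMSpec(3, 4, "max_rl", "per_context"))["covariate"] == 24
        assert n_parameters_breakdown(
            HMMSpec(3, 2, "phase_categorical"))["covariate"] == 12


class TestFitAndDecode:
    def test_fit_beats_generating_parameters_and_is_deterministic(
            self, gen_params, small_dataset):
        data, _ = small_dataset
        spec = HMMSpec(3, 2, "none")
        fit1 = fit_hmm(data, spec, n_starts=1, seed=2)
        fit2 = fit_hmm(data, spec, n_starts=1, seed=2)
        assert fit1.loglik == fit2.loglik
        assert np.array_equal(fit1.theta, fit2.theta)
        p = hmm.HMMParams(**{k: np.asarray(v, dtype=float)
                             for k, v in gen_params.items()
                             if k != "beta"},
                          beta=np.zeros((0, 2, 3, 3)))
        assert fit1.loglik >= mixture_loglik(data, p) - 1e-6
        assert fit1.aic == pytest.approx(-2 * fit1.loglik + 2 * fit1.n_parameters)

    def test_two_state_emission_recovery(self):
        from fincee import synthetic
        params = {
            "time_shape": [16.0, 6.0], "time_rate": [16 / 400, 6 / 120],
            "depth_shape": [25.0, 5.0], "depth_rate": [25 / 150, 5 / 12],
            "lunge_rate": [4.0, 0.2], "speed_shape": [9.0, 16.0],
            "speed_rate": [9 / 1.5, 16 / 2.5], "mu": [0.0, 0.0],
            "kappa": [0.5, 3.0], "eta": np.full((1, 2, 2), -1.5),
            "delta": [[0.5, 0.5]], "pi": [1.0],
        }
        data, _ = synthetic.simulate_dives(params, None, 20, 150, seed=33)
        fit = fit_hmm(data, HMMSpec(2, 1, "none"), n_starts=2, seed=1)
        p = fit.params
        means = {
            "time": (p.time_shape / p.time_rate, [400, 120]),
            "depth": (p.depth_shape / p.depth_rate, [150, 12]),
            "lunges": (p.lunge_rate, [4.0, 0.2]),
            "speed": (p.speed_shape / p.speed_rate, [1.5, 2.5]),
        }
        for name, (est, true) in means.items():
            assert np.allclose(est, true, rtol=0.10), (name, est, true)

    def test_states_canonical_deepest_first(self, small_dataset):
        data, _ = small_dataset
        fit = fit_hmm(data, HMMSpec(3, 1, "none"), n_starts=1, seed=0)
        depth_means = fit.params.depth_shape / fit.params.depth_rate
        assert np.all(np.diff(depth_means) <= 0)

    def test_select_model_reports_aic_definition_and_tie_break(self, small_dataset):
        data, _ = small_dataset
        specs = [HMMSpec(3, 1, "none"), HMMSpec(3, 2, "none")]
        fits = hmm.select_model(data, specs, n_starts=1, seed=3)
        for f in fits:
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_parameters)
        assert fits[0].aic <= fits[-1].aic

    def test_local_decode_posteriors_normalized(self, small_dataset):
        data, _ = small_dataset
        fit = fit_hmm(data, HMMSpec(3, 2, "none"), n_starts=1, seed=4)
        dec = local_decode(fit, data)
        assert np.allclose(dec.context_posterior.sum(axis=1), 1.0)
        assert np.allclose(dec.state_posterior.sum(axis=1), 1.0)
        assert dec.states.between(1, 3).all()

    def test_single_context_posterior_is_one(self, small_dataset):
        data, _ = small_dataset
        fit = fit_hmm(data, HMMSpec(3, 1, "none"), n_starts=1, seed=5)
        dec = local_decode(fit, data)
        assert np.allclose(dec.context_posterior.to_numpy(), 1.0)

    def test_decode_matches_brute_force_enumeration(self):
        # T=3, N=2, K=2: posteriors by explicit path x context enumeration
        import itertools

        from scipy import stats as sps
        p = toy_hmm_params(2, 2, beta=0.5, seed=14)
        seq = toy_sequence(3, seed=15, with_cov=True)
        x = seq["covariate"].to_numpy()

        def emis(t, i):
            r = seq.iloc[t]
            return np.exp(
                sps.gamma.logpdf(r["dive_time_s"], p.time_shape[i], scale=1 / p.time_rate[i])
                + sps.gamma.logpdf(r["max_depth_m"], p.depth_shape[i], scale=1 / p.depth_rate[i])
                + sps.poisson.logpmf(r["lunges"], p.lunge_rate[i])
                + sps.gamma.logpdf(r["speed_ms"], p.speed_shape[i], scale=1 / p.speed_rate[i])
                + sps.vonmises.logpdf(r["turn_angle_rad"], p.kappa[i], loc=p.mu[i]))

        def trow(k, t, i):
            logits = p.eta[k, i].copy() + p.beta[0, k, i] * x[t]
            logits[i] = 0.0
            e = np.exp(logits - logits.max())
            return e / e.sum()

        joint = np.zeros((2,) + (2, 2, 2))  # context x path
        for k in range(2):
            for path in itertools.product(range(2), repeat=3):
                pr = p.pi[k] * p.delta[k, path[0]] * emis(0, path[0])
                for t in range(1, 3):
                    pr *= trow(k, t, path[t - 1])[path[t]] * emis(t, path[t])
                joint[(k,) + path] = pr
        joint /= joint.sum()
        # P(state_t = s | data) by summing the joint over contexts and paths
        expect = np.zeros((3, 2))
        for k in range(2):
            for path in itertools.product(range(2), repeat=3):
                for t in range(3):
                    expect[t, path[t]] += joint[(k,) + path]
        ctx_expect = joint.sum(axis=(1, 2, 3))

        spec = HMMSpec(2, 2, "custom")
        fake_fit = hmm.HMMFit(
            spec=spec, params=p, theta=hmm._pack(p, spec),
            param_names=hmm.param_names(spec), loglik=0.0,
            n_parameters=n_parameters(spec), aic=0.0, cov_scale=(0.0, 1.0),
            starts=pd.DataFrame(), best_start=0, converged=True)
        dec = local_decode(fake_fit, seq)
        assert np.allclose(dec.state_posterior.to_numpy(), expect, atol=1e-10)
        assert np.allclose(dec.context_posterior.to_numpy()[0], ctx_expect,
                           atol=1e-10)


class TestWaldCI:
    def test_interval_contains_estimate_and_z_quantile(self, small_dataset):
        data, _ = small_dataset
        fit = fit_hmm(data, HMMSpec(3, 1, "none"), n_starts=1, seed=6)
        ci = wald_ci(fit, level=0.95)
        assert ((ci["lower"] <= ci["estimate"])
                & (ci["estimate"] <= ci["upper"])).all()
        halfwidth = (ci["upper"] - ci["lower"]) / 2
        assert np.allclose(halfwidth, 1.959964 * ci["se"], rtol=1e-4)

    def test_poisson_rate_interval_matches_analytic_fisher_information(self):
        # N=1: the lunge-rate block is independent; the observed information
        # for log(lambda) is n * lambda, so the CI is log(lam) +- z/sqrt(n*lam)
        seq = toy_sequence(400, seed=20)
        fit = fit_hmm(seq, HMMSpec(1, 1, "none"), n_starts=1, seed=0)
        lam = fit.params.lunge_rate[0]
        assert lam == pytest.approx(seq["lunges"].mean(), rel=1e-4)
        ci = wald_ci(fit)
        row = ci[ci["parameter"] == "log_lunge_rate[1]"].iloc[0]
        se_expect = 1.0 / np.sqrt(len(seq) * lam)
        assert row["se"] == pytest.approx(se_expect, rel=1e-3)


def _state_dict(p, i):
    return {"time_shape": p.time_shape[i], "time_rate": p.time_rate[i],
            "depth_shape": p.depth_shape[i], "depth_rate": p.depth_rate[i],
            "lunge_rate": p.lunge_rate[i], "speed_shape": p.speed_shape[i],
            "speed_rate": p.speed_rate[i], "mu": p.mu[i], "kappa": p.kappa[i]}
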