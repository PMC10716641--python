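import numpy as np
import pandas as pd
import pytest

from fincee.severity import (breslow_partial_loglik, build_event_table,
                             fit_hazards, mahalanobis_series, ph_test,
                             response_function)


class TestMahalanobis:
    def _series(self, window_means_x, window_means_y):
        # one sample per 1-s window
        n = len(window_means_x)
        return pd.DataFrame({"time_s": np.arange(n) + 0.0,
                             "mx": window_means_x, "my": window_means_y})

    def test_baseline_mean_window_distance_zero(self):
        s = self._series([1.0, 3.0, 2.0, 2.0], [4.0, 6.0, 5.0, 5.0])
        res = mahalanobis_series(s, baseline_interval=(0, 3), window_s=1.0)
        # 4th window equals the baseline mean (2, 5)
        assert res.distances[3] == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_distance_with_diagonal_covariance(self):
        # baseline windows with sample covariance exactly diag(4, 9)
        sx = np.sqrt(3.0)
        sy = np.sqrt(27.0) / 2
        bx = [-sx, -sx, sx, sx]
        by = [-sy, sy, -sy, sy]
        s = self._series(bx + [2.0], by + [3.0])
        res = mahalanobis_series(s, baseline_interval=(0, 4), window_s=1.0)
        base = s[["mx", "my"]].iloc[:4]
        assert np.allclose(np.cov(base.T, ddof=1), np.diag([4.0, 9.0]))
        # deviation (2, 3): sqrt(4/4 + 9/9) = sqrt(2)
        assert res.distances[4] == pytest.approx(np.sqrt(2.0), abs=1e-10)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        s = pd.DataFrame({"time_s": np.arange(40.0),
                          "a": rng.normal(0, 1, 40), "b": rng.normal(5, 2, 40)})
        r1 = mahalanobis_series(s, (0, 20), window_s=1.0)
        s2 = s.assign(a=10 * s["a"] - 3, b=0.1 * s["b"] + 100)
        r2 = mahalanobis_series(s2, (0, 20), window_s=1.0)
        assert np.allclose(r1.distances, r2.distances, atol=1e-8)

    def test_short_baseline_forces_regularization(self):
        s = pd.DataFrame({"time_s": np.arange(6.0),
                          "a": [1, 2, 1.5, 3, 4, 5],
                          "b": [0, 1, 0.5, 2, 2, 3],
                          "c": [2, 1, 1.5, 0, 1, 2]})
        with pytest.warns(UserWarning):
            res = mahalanobis_series(s, (0, 2), window_s=1.0)
        assert res.regularized
        assert np.isfinite(res.distances).all()


class TestEventTable:
    def test_paper_fixture_counts(self, fixture_tables):
        ev = build_event_table(fixture_tables.severity_table)
        assert ev["whale_id"].nunique() == 15          # exposure CEEs only
        assert len(ev) == 30                            # 15 CEEs x 2 strata
        assert (ev.groupby("whale_id").size() == 2).all()
        assert ev[ev["event"] == 1]["whale_id"].nunique() == 5
        # moderate responders also fire the low stratum at the same dose
        assert ev.groupby("stratum")["event"].sum().to_dict() == {
            "low": 5, "moderate": 4}

    def test_known_rows(self, fixture_tables):
        ev = build_event_table(fixture_tables.severity_table).set_index(
            ["whale_id", "stratum"])
        # severity 6 at cSEL 111: moderate event, implied low event, same dose
        assert ev.loc[("bp10_247a", "moderate")].tolist()[:2] == [111.0, 1]
        assert ev.loc[("bp10_247a", "low")].tolist()[:2] == [111.0, 1]
        # severity 2 at 145: low event only; moderate censored at the print
        assert ev.loc[("bp10_239a", "low"), "event"] == 1
        assert ev.loc[("bp10_239a", "moderate"), "event"] == 0
        # unscored "moderate change" coded into the moderate band
        assert ev.loc[("bp12_294a", "moderate")].tolist()[:2] == [101.0, 1]

    def test_switchable_conventions(self, fixture_tables):
        # without the implied-low and unscored-moderate conventions only the
        # printed scores count: one low-band (score 2) and three moderate
        ev = build_event_table(fixture_tables.severity_table,
                               moderate_implies_low=False,
                               include_unscored_moderate=False)
        assert ev.groupby("stratum")["event"].sum().to_dict() == {
            "low": 1, "moderate": 3}

    def test_all_censored_input(self, fixture_tables):
        sev = fixture_tables.severity_table.copy()
        sev["change"] = "no"
        sev["severity_score"] = np.nan
        ev = build_event_table(sev)
        assert ev["event"].sum() == 0
        assert (ev["dose"] > 0).all()


class TestHazards:
    def test_two_event_partial_likelihood_hand_oracle(self):
        # two events, no ties, one binary covariate, one stratum:
        # ll = [b*x1 - log(sum_{risk at t1} e^{b x})] + [b*x2 - log(...)]
        ev = pd.DataFrame({
            "whale_id": list("abcd"), "stratum": "low",
            "dose": [100.0, 120.0, 130.0, 140.0],
            "event": [1, 1, 0, 0],
            "signal_type": ["PRN", "MFAS", "PRN", "MFAS"],
        })
        fit = fit_hazards(ev, ["signal_type"])
        b = fit.coefficients["coef"].iloc[0]
        x = np.array([1.0, 0.0, 1.0, 0.0])  # PRN dummy
        hand = ((b * x[0] - np.log(np.exp(b * x).sum()))
                + (b * x[1] - np.log(np.exp(b * x[1:]).sum())))
        assert fit.loglik == pytest.approx(hand, abs=1e-8)
        # and the same expression evaluated by the package's evaluator
        assert breslow_partial_loglik(fit.design, fit.covariate_columns,
                                      np.array([b])) == pytest.approx(hand, abs=1e-10)

    def test_null_model_aic_definition(self, fixture_tables):
        ev = build_event_table(fixture_tables.severity_table)
        null = fit_hazards(ev, None)
        assert null.aic == pytest.approx(-2 * null.loglik)
        assert len(null.coefficients) == 0

    def test_duplicated_dataset_same_coefficients(self, fixture_tables):
        ev = build_event_table(fixture_tables.severity_table)
        fit1 = fit_hazards(ev, ["signal_type"])
        ev2 = pd.concat([ev, ev], ignore_index=True)
        fit2 = fit_hazards(ev2, ["signal_type"])
        assert fit2.coefficients["coef"].iloc[0] == pytest.approx(
            fit1.coefficients["coef"].iloc[0], abs=1e-6)

    def test_matches_r_survival_reference_values(self, fixture_tables):
        # frozen from an independent fit of the same event table in
        # R survival::coxph (Breslow ties, stratified)
        ev = build_event_table(fixture_tables.severity_table)
        fit = fit_hazards(ev, ["signal_type"])
        assert fit.coefficients["coef"].iloc[0] == pytest.approx(1.08004, abs=1e-4)
        assert fit.coefficients["se_model"].iloc[0] == pytest.approx(0.67463, abs=1e-4)
        assert fit.loglik == pytest.approx(-22.00973, abs=1e-4)
        null = fit_hazards(ev, None)
        assert null.loglik == pytest.approx(-23.19182, abs=1e-4)

    def test_jackknife_se_positive(self, fixture_tables):
        ev = build_event_table(fixture_tables.severity_table)
        fit = fit_hazards(ev, ["signal_type"])
        assert (fit.coefficients["se_jackknife"] > 0).all()

    def test_simulation_recovery_of_log_hazard_ratio(self):
        # proportional-hazards generator: unit-exponential baseline on the
        # dose axis, hazard ratio exp(beta) for PRN, censoring at dose 2
        beta_true = 0.8
        rng = np.random.default_rng(17)
        est = []
        for _ in range(40):
            n = 60
            prn = rng.integers(0, 2, n)
            u = rng.exponential(1.0, n) / np.exp(beta_true * prn)
            dose = np.minimum(u, 2.0)
            event = (u < 2.0).astype(int)
            ev = pd.DataFrame({
                "whale_id": [f"w{i}" for i in range(n)], "stratum": "low",
                "dose": dose, "event": event,
                "signal_type": np.where(prn == 1, "PRN", "MFAS")})
            est.append(fit_hazards(ev, ["signal_type"]).coefficients["coef"].iloc[0])
        bias = np.mean(est) - beta_true
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(bias) < 3 * mc_se + 0.05


class TestPHTest:
    def test_residuals_sum_to_zero_at_mle(self, fixture_tables):
        ev = build_event_table(fixture_tables.severity_table)
        fit = fit_hazards(ev, ["signal_type"])
        res = ph_test(fit)
        assert np.all(np.abs(res.residual_score_sum) < 1e-4)

    def test_fixture_global_test_not_significant(self, fixture_tables):
        # reference printed value for this model: global p = 0.186
        ev = build_event_table(fixture_tables.severity_table)
        fit = fit_hazards(ev, ["signal_type"])
        res = ph_test(fit)
        assert 0.0 <= res.global_p <= 1.0
        assert res.global_p > 0.05
        assert res.global_p == pytest.approx(0.186, abs=0.02)

    def test_undefined_without_events(self):
        ev = pd.DataFrame({"whale_id": ["a", "b"], "stratum": "low",
                           "dose": [10.0, 20.0], "event": [0, 0],
                           "signal_type": ["PRN", "MFAS"]})
        with pytest.raises(ValueError):
            ph_test(fit_hazards(ev, None))


class TestResponseFunction:
    def test_single_event_breslow_step_closed_form(self):
        # one event among three at risk, beta = 0 profile:
        # H0 jumps by 1/3 at the event dose -> response 1 - exp(-1/3)
        ev = pd.DataFrame({"whale_id": list("abc"), "stratum": "low",
                           "dose": [110.0, 150.0, 160.0], "event": [1, 0, 0],
                           "signal_type": ["MFAS"] * 3})
        fit = fit_hazards(ev, None)
        curves = response_function(fit, ev, pd.DataFrame(index=[0]),
                                   doses=np.array([100.0, 110.0, 140.0]))
        cur = curves[("low",)]
        assert cur["response_prob"].iloc[0] == 0.0  # before the first event
        assert cur["response_prob"].iloc[1] == pytest.approx(1 - np.exp(-1 / 3))
        assert cur["response_prob"].iloc[2] == pytest.approx(1 - np.exp(-1 / 3))

    def test_curves_monotone_and_higher_for_prn(self, fixture_tables):
        ev = build_event_table(fixture_tables.severity_table)
        fit = fit_hazards(ev, ["signal_type"])
        curves = response_function(fit, ev,
                                   pd.DataFrame({"signal_type": ["MFAS", "PRN"]}))
        for cur in curves.values():
            assert (np.diff(cur["response_prob"]) >= -1e-12).all()
        for stratum in ("low", "moderate"):
            m = curves[(stratum, "MFAS")]["response_prob"]
            p = curves[(stratum, "PRN")]["response_prob"]
            assert (p >= m - 1e-12).all()

    def test_null_model_matches_kaplan_meier_complement(self):
        # beta = 0, tie-free: 1 - exp(-H_breslow) vs 1 - KM are equal in the
        # first-order (1/n) sense; compare with the Nelson-Aalen identity
        ev = pd.DataFrame({"whale_id": list("abcdef"), "stratum": "low",
                           "dose": [100.0, 110.0, 120.0, 130.0, 140.0, 150.0],
                           "event": [1, 0, 1, 0, 1, 0],
                           "signal_type": ["MFAS"] * 6})
        fit = fit_hazards(ev, None)
        doses = np.array([105.0, 125.0, 145.0])
        cur = response_function(fit, ev, pd.DataFrame(index=[0]),
                                doses=doses)[("low",)]
        na = np.array([1 / 6, 1 / 6 + 1 / 4, 1 / 6 + 1 / 4 + 1 / 2])
        assert np.allclose(cur["response_prob"], 1 - np.exp(-na), atol=1e-10)

    def test_extrapolation_clamped_and_flagged(self, fixture_tables):
        ev = build_event_table(fixture_tables.severity_table)
        fit = fit_hazards(ev, ["signal_type"])
        curves = response_function(fit, ev,
                                   pd.DataFrame({"signal_type": ["MFAS"]}),
                                   doses=np.array([50.0, 130.0, 300.0]))
        cur = curves[("low", "MFAS")]
        assert cur["clamped"].tolist() == [True, False, True]
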