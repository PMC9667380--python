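"""Repeated-measures model, GLMs, Park test, link diagnostics, missingness
regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from dataclasses import replace

import trialcea as tc
from trialcea.config import AnalysisConfig, FOLLOWUP_WAVES
from trialcea.estimation import (
    EstimationError,
    fit_repeated_measures,
    fit_outcome_glm,
    modified_park_test,
    link_diagnostics,
    missingness_model,
    _design,
)
from trialcea.costing import cost_service_use

from conftest import make_deterministic_cost_dataset


def _attach_costs(dataset, scenario, breakdown):
    priced = cost_service_use(dataset, scenario.unit_costs)
    m3 = priced.df["wave"] == 3
    priced.df.loc[m3, "cost_aud"] = (
        priced.df.loc[m3, "cost_aud"]
        + priced.df.loc[m3, "arm"].map(breakdown.average_per_participant).astype(float)
    )
    return priced


class TestRepeatedMeasures:
    def test_zero_noise_exact_recovery(self):
        """Constant planted arm effects come back exactly at every wave."""
        ds = make_deterministic_cost_dataset({1: 0.0, 2: -500.0, 3: 250.0})
        est = fit_repeated_measures(ds, "cost")
        for w in FOLLOWUP_WAVES:
            assert est.difference(2, 1, w).diff == pytest.approx(-500.0, abs=1e-6)
            assert est.difference(3, 1, w).diff == pytest.approx(250.0, abs=1e-6)
        assert est.difference(2, 1).diff == pytest.approx(-2000.0, abs=1e-5)

    def test_gls_oracle_equivalence_on_complete_data(self, scenario, full_trial, breakdown):
        """With complete data the profiled REML fixed effects equal the
        closed-form GLS solution at the estimated covariance."""
        priced = _attach_costs(full_trial, scenario, breakdown)
        est = fit_repeated_measures(priced, "utility")
        Y, cov, _, arms = _design(priced, "utility")
        n, K = Y.shape
        P = 3 * K + cov.shape[1]
        X = np.zeros((n, K, P))
        for k in range(K):
            X[np.arange(n), k, [(a - 1) * K + k for a in arms]] = 1.0
        X[:, :, 3 * K:] = cov[:, None, :]
        W = np.linalg.inv(est.sigma)
        A = np.einsum("nkp,kl,nlq->pq", X, W, X)
        b = np.einsum("nkp,kl,nl->p", X, W, Y)
        beta_gls = np.linalg.solve(A, b)
        assert np.allclose(est.beta, beta_gls, rtol=1e-6)

    def test_antisymmetry_of_comparisons(self, scenario, observed_trial, breakdown):
        priced = _attach_costs(observed_trial, scenario, breakdown)
        est = fit_repeated_measures(priced, "utility")
        for w in list(FOLLOWUP_WAVES) + [None]:
            d23 = est.difference(2, 3, w)
            d32 = est.difference(3, 2, w)
            assert d23.diff == pytest.approx(-d32.diff)
            assert d23.se == pytest.approx(d32.se)
            # 2v1 minus 3v1 equals 2v3
            assert est.difference(2, 1, w).diff - est.difference(3, 1, w).diff == \
                pytest.approx(d23.diff, abs=1e-8)

    def test_partial_followup_participants_contribute(self, scenario, observed_trial,
                                                      breakdown):
        priced = _attach_costs(observed_trial, scenario, breakdown)
        est = fit_repeated_measures(priced, "cost")
        # far more participants enter than the all-wave completers
        n_complete = (
            priced.df[priced.df["wave"] > 0]
            .groupby("participant_id")["cost_aud"]
            .apply(lambda s: s.notna().all())
            .sum()
        )
        assert est.n_participants > n_complete + 50
        assert est.converged

    def test_all_missing_cell_is_an_error(self, scenario, observed_trial, breakdown):
        priced = _attach_costs(observed_trial, scenario, breakdown)
        df = priced.df.copy()
        df.loc[(df["arm"] == 2) & (df["wave"] == 12), "cost_aud"] = np.nan
        with pytest.raises(EstimationError, match="arm 2 has no data at wave 12"):
            fit_repeated_measures(tc.TrialDataset(df), "cost")

    def test_ci_brackets_point_estimate(self, scenario, observed_trial, breakdown):
        priced = _attach_costs(observed_trial, scenario, breakdown)
        est = fit_repeated_measures(priced, "cost")
        for (a, b), waves in est.per_wave.items():
            for e in waves.values():
                assert e.ci_low <= e.diff <= e.ci_high


class TestGLMs:
    def _table(self, n=5000, diff=-2858.0, seed=0):
        rng = np.random.default_rng(seed)
        arm = np.repeat([1, 2, 3], n // 3 + 1)[:n]
        mu = 9000.0 + diff * (arm == 2) + 1500.0 * (arm == 3)
        shape = 1.2
        y = rng.gamma(shape, mu / shape)
        return pd.DataFrame(
            {
                "arm": arm,
                "sex": rng.choice(["female", "male"], n),
                "country": rng.choice(["US", "Australia", "other"], n),
                "total_3_12": y,
                "cost_0": rng.gamma(1.0, 2000.0, n),
            }
        )

    def test_gamma_identity_recovers_planted_difference(self):
        t = self._table()
        ests, fit = fit_outcome_glm(t, "total_3_12", "cost_0", "gamma")
        e = ests[(2, 1)]
        assert abs(e.diff - (-2858.0)) < 2 * e.se
        assert fit is not None

    def test_constant_outcome_zero_difference_zero_se(self):
        t = self._table(n=300)
        t["total_3_12"] = 777.0
        ests, _ = fit_outcome_glm(t, "total_3_12", "cost_0", "gamma")
        assert ests[(2, 1)].diff == 0.0 and ests[(2, 1)].se == 0.0

    def test_gaussian_less_precise_under_multiplicative_noise(self):
        t = self._table(n=4000, seed=3)
        gamma_e, _ = fit_outcome_glm(t, "total_3_12", "cost_0", "gamma")
        gauss_e, _ = fit_outcome_glm(t, "total_3_12", "cost_0", "gaussian")
        assert abs(gamma_e[(2, 1)].diff - gauss_e[(2, 1)].diff) < 2 * gauss_e[(2, 1)].se
        assert gamma_e[(2, 1)].se < gauss_e[(2, 1)].se

    def test_cost_and_qaly_wrappers_on_completers(self, participant_table):
        cc = participant_table.dropna(subset=["total_3_12", "qaly"])
        cost_ests, cost_fit = tc.fit_cost_glm(cc)
        qaly_ests, qaly_fit = tc.fit_qaly_glm(cc)
        for ests in (cost_ests, qaly_ests):
            assert set(ests) == {(2, 1), (3, 1), (2, 3)}
            for e in ests.values():
                assert np.isfinite(e.diff) and e.ci_low <= e.diff <= e.ci_high
        # positive-support families: fitted means stay positive
        assert (cost_fit.fittedvalues > 0).all()
        assert (qaly_fit.fittedvalues > 0).all()

    def test_nonpositive_outcomes_shift_policy(self):
        t = self._table(n=300)
        t.loc[t.index[:5], "total_3_12"] = 0.0
        cfg = AnalysisConfig(zero_cost_policy="shift")
        ests, _ = fit_outcome_glm(t, "total_3_12", "cost_0", "gamma", cfg)
        assert np.isfinite(ests[(2, 1)].diff)


class TestModifiedParkTest:
    def test_gamma_variance_power_recovered(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 5, 2000)
        mu = 100 + 50 * x
        y = rng.gamma(1.0, mu)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rep = modified_park_test(y, fit.fittedvalues)
        assert abs(rep.park_coefficient - 2.0) < 2 * rep.park_se
        assert rep.recommended_family == "gamma"

    def test_homoskedastic_normal_power_zero(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 5, 2000)
        mu = 100 + 50 * x
        y = mu + rng.normal(0, 25, 2000)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rep = modified_park_test(y, fit.fittedvalues)
        assert abs(rep.park_coefficient) < 2 * rep.park_se
        assert rep.recommended_family == "gaussian"

    def test_perfect_fit_is_degenerate(self):
        y = np.array([1.0, 2.0, 3.0])
        with pytest.raises(EstimationError, match="perfect fit"):
            modified_park_test(y, y)

    def test_nonpositive_predictions_rejected(self):
        with pytest.raises(EstimationError, match="positive"):
            modified_park_test(np.ones(5), np.array([1, 1, -1, 1, 1.0]))


class TestLinkDiagnostics:
    def test_type_i_error_roughly_nominal(self):
        """Correctly specified identity link: Pregibon and Hosmer-Lemeshow
        reject near 5%; the Pearson check never exceeds it (least-squares
        residuals are orthogonal to predictions by construction, so the
        raw-residual correlation can only be conservative there)."""
        rng = np.random.default_rng(5)
        n, reps = 300, 300
        rej = np.zeros(3)
        for _ in range(reps):
            x = rng.uniform(1, 4, n)
            y = 10 + 3 * x + rng.normal(0, 1, n)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            r = link_diagnostics(fit)
            rej += [r.pearson_p < 0.05, r.pregibon_p < 0.05, r.hosmer_lemeshow_p < 0.05]
        rates = rej / reps
        assert np.all(rates < 0.12)
        assert rates[1] > 0.005 and rates[2] > 0.005

    def test_pregibon_detects_wrong_link(self):
        rng = np.random.default_rng(6)
        n, reps, hits = 300, 60, 0
        for _ in range(reps):
            x = rng.uniform(0, 2, n)
            y = np.exp(1 + 1.2 * x) + rng.normal(0, 2, n)  # log-link truth
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            hits += link_diagnostics(fit).pregibon_p < 0.05
        assert hits / reps > 0.5

    def test_constant_predictor_zero_correlation(self):
        rng = np.random.default_rng(7)
        y = rng.normal(10, 1, 50)
        fit = sm.OLS(y, np.ones((50, 1))).fit()
        r = link_diagnostics(fit)
        assert r.pearson_p == 1.0

    def test_small_sample_rejected(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=10)
        fit = sm.OLS(y, np.ones((10, 1))).fit()
        with pytest.raises(EstimationError, match="at least"):
            link_diagnostics(fit)


class TestMissingnessModel:
    def test_null_mechanism_gives_unit_odds_ratios(self):
        from trialcea.simulate import MissingnessModel, default_scenario, generate_trial, \
            apply_missingness

        sc = replace(
            default_scenario(seed=31),
            arm_sizes=(700, 700, 600),
            missingness=MissingnessModel(female_or=1.0, completion_correlation=0.95),
        )
        obs = apply_missingness(generate_trial(sc), sc)
        out = missingness_model(obs)
        assert out.loc["female", "ci_low"] <= 1.0 <= out.loc["female", "ci_high"]

    def test_sex_effect_recovered_with_nested_completion(self):
        """Near-comonotone waves make overall completeness follow the
        wave-level logistic model, so the generating OR is recovered."""
        from trialcea.simulate import MissingnessModel, default_scenario, generate_trial, \
            apply_missingness

        sc = replace(
            default_scenario(seed=32),
            arm_sizes=(1700, 1700, 1600),
            sex_fraction=0.5,
            missingness=MissingnessModel(female_or=0.5, completion_correlation=0.999),
        )
        obs = apply_missingness(generate_trial(sc), sc)
        out = missingness_model(obs)
        b = np.log(out.loc["female", "odds_ratio"])
        se = (np.log(out.loc["female", "ci_high"]) - np.log(out.loc["female", "ci_low"])) / (2 * 1.96)
        assert abs(b - np.log(0.5)) < 2 * se

    def test_all_complete_flagged_degenerate(self, full_trial):
        with pytest.raises(EstimationError, match="degenerate"):
            missingness_model(full_trial)
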