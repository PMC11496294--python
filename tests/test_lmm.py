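import subprocess
import textwrap
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dmtpower as dp
from dmtpower.lmm import _Workspace, fit_lmm


def make_data(n_subj=3, times=(0.0, 0.25, 0.5, 0.75), seed=0, beta=(1.0, 2.0, 0.3, 0.5),
              sigma_b=1.5, sigma=0.8, phi=0.4):
    """Simulate directly from the fitted model's own law (not the state-space
    model) so parameter recovery has a well-defined truth."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times)
    m = t.size
    rows = []
    R = phi ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
    for i in range(n_subj):
        arm = i % 2
        X = np.column_stack([np.ones(m), t, np.full(m, arm), t * arm])
        eps = sigma * (L @ rng.standard_normal(m))
        y = X @ np.asarray(beta) + sigma_b * rng.standard_normal() + eps
        rows.append(
            pd.DataFrame(
                {"participant_id": i, "arm": float(arm), "time_years": t, "value": y}
            )
        )
    return pd.concat(rows, ignore_index=True)


def dense_oracle(df, gamma, phi, reml=False):
    """Brute-force GLS and Gaussian log-density with an explicit full
    covariance matrix; the independent check for the blocked likelihood."""
    df = df.sort_values(["participant_id", "time_years"], kind="stable")
    X_list, blocks = [], []
    y = df["value"].to_numpy()
    for _, g in df.groupby("participant_id", sort=True):
        t = g["time_years"].to_numpy()
        a = g["arm"].to_numpy()
        m = len(g)
        X_list.append(np.column_stack([np.ones(m), t, a, t * a]))
        R = phi ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        blocks.append(gamma * np.ones((m, m)) + R)
    X = np.vstack(X_list)
    from scipy.linalg import block_diag

    C = block_diag(*blocks)
    Ci = np.linalg.inv(C)
    XtCiX = X.T @ Ci @ X
    beta = np.linalg.solve(XtCiX, X.T @ Ci @ y)
    r = y - X @ beta
    N = len(y)
    denom = N - 4 if reml else N
    sigma2 = (r @ Ci @ r) / denom
    sign, logdetC = np.linalg.slogdet(C)
    ll = -0.5 * (denom * np.log(2 * np.pi * sigma2) + logdetC + denom)
    if reml:
        ll -= 0.5 * np.linalg.slogdet(XtCiX)[1]
    return beta, sigma2, ll


class TestLikelihoodOracle:
    @pytest.mark.parametrize("gamma,phi", [(0.5, 0.0), (2.0, 0.4), (0.1, -0.3), (3.0, 0.8)])
    @pytest.mark.parametrize("reml", [False, True])
    def test_blocked_equals_dense(self, gamma, phi, reml):
        df = make_data(n_subj=6, times=(0.0, 0.3, 0.6, 1.0), seed=11)  # 24 obs
        ws = _Workspace(
            df["participant_id"].to_numpy(),
            df["time_years"].to_numpy(),
            df["arm"].to_numpy(),
            df["value"].to_numpy(),
        )
        nll, beta, sigma2, _ = ws.profile(gamma, phi, reml=reml)
        beta_o, sigma2_o, ll_o = dense_oracle(df, gamma, phi, reml=reml)
        assert np.allclose(beta, beta_o, atol=1e-8)
        assert sigma2 == pytest.approx(sigma2_o, abs=1e-8)
        assert -nll == pytest.approx(ll_o, abs=1e-8)

    def test_unbalanced_schedules(self):
        # participants on different schedules exercise the multi-pattern path
        df1 = make_data(n_subj=4, times=(0.0, 0.5, 1.0), seed=1)
        df2 = make_data(n_subj=4, times=(0.0, 0.25, 0.5, 0.75, 1.0), seed=2)
        df2["participant_id"] += 10
        df = pd.concat([df1, df2], ignore_index=True)
        ws = _Workspace(
            df["participant_id"].to_numpy(),
            df["time_years"].to_numpy(),
            df["arm"].to_numpy(),
            df["value"].to_numpy(),
        )
        nll, beta, sigma2, _ = ws.profile(1.3, 0.5)
        beta_o, sigma2_o, ll_o = dense_oracle(df, 1.3, 0.5)
        assert np.allclose(beta, beta_o, atol=1e-8)
        assert -nll == pytest.approx(ll_o, abs=1e-8)


class TestFitLmm:
    def test_noise_free_interpolation(self):
        t = np.array([0.0, 0.5, 1.0, 1.5])
        rows = []
        for i in range(6):
            arm = i % 2
            y = 1.0 + 2.0 * t + 0.5 * arm * t
            rows.append(pd.DataFrame(
                {"participant_id": i, "arm": arm, "time_years": t, "value": y}))
        fit = fit_lmm(pd.concat(rows, ignore_index=True))
        assert np.allclose(fit.beta, [1.0, 2.0, 0.0, 0.5], atol=1e-8)
        assert fit.var_intercept == 0.0 and fit.var_resid == 0.0

    def test_parameter_recovery(self):
        df = make_data(
            n_subj=500, times=tuple(np.linspace(0, 1, 8)), seed=42,
            sigma_b=2.0, sigma=1.0, phi=0.5,
        )
        fit = fit_lmm(df)
        assert fit.var_intercept == pytest.approx(4.0, rel=0.15)
        assert fit.var_resid == pytest.approx(1.0, rel=0.10)
        assert fit.phi == pytest.approx(0.5, abs=0.05)
        assert np.allclose(fit.beta, [1.0, 2.0, 0.3, 0.5], atol=0.35)

    def test_phi_zero_matches_independent_fit(self):
        df = make_data(n_subj=30, seed=3, phi=0.0)
        f_ind = fit_lmm(df, correlation="independent")
        ws = _Workspace(
            df["participant_id"].to_numpy(), df["time_years"].to_numpy(),
            df["arm"].to_numpy(), df["value"].to_numpy(),
        )
        gamma_hat = f_ind.var_intercept / f_ind.var_resid
        nll0, *_ = ws.profile(gamma_hat, 0.0)
        assert -nll0 == pytest.approx(f_ind.loglik, abs=1e-5)
        f_ar = fit_lmm(df, correlation="ar1")
        assert f_ar.loglik >= f_ind.loglik - 1e-6  # AR(1) nests independence

    def test_relabeling_invariance(self):
        df = make_data(n_subj=20, seed=5)
        fit0 = fit_lmm(df)
        relabeled = df.copy()
        relabeled["participant_id"] = 999 - relabeled["participant_id"]
        fit1 = fit_lmm(relabeled)
        assert np.allclose(fit0.beta, fit1.beta, atol=1e-6)
        assert fit0.loglik == pytest.approx(fit1.loglik, abs=1e-6)

    def test_arm_swap_flips_interaction_sign(self):
        df = make_data(n_subj=20, seed=6)
        fit0 = fit_lmm(df)
        swapped = df.assign(arm=1.0 - df["arm"])
        fit1 = fit_lmm(swapped)
        assert fit1.beta[3] == pytest.approx(-fit0.beta[3], abs=1e-5)
        assert abs(fit1.t_interaction) == pytest.approx(abs(fit0.t_interaction), abs=1e-3)

    def test_singular_designs_rejected(self):
        df = make_data(n_subj=6)
        with pytest.raises(dp.SingularDesignError):
            fit_lmm(df.assign(arm=0.0))  # one arm empty
        t0 = df[df["time_years"] == 0.0]
        with pytest.raises(dp.LmmError):
            fit_lmm(t0)

    def test_string_arm_labels_accepted(self):
        df = make_data(n_subj=10, seed=8)
        lab = df.assign(arm=np.where(df["arm"] > 0, "treatment", "placebo"))
        fit_str = fit_lmm(lab)
        fit_num = fit_lmm(df)
        assert np.allclose(fit_str.beta, fit_num.beta, atol=1e-6)


class TestInteractionTest:
    def test_between_within_df(self, small_trial):
        fit = fit_lmm(small_trial.records)
        t, df_, p = dp.test_interaction(fit)
        assert df_ == fit.n_obs - fit.n_participants - 2
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df_), rel=1e-12)

    def test_null_beta_gives_p_near_one(self):
        # construct data where the interaction estimate is exactly zero by
        # symmetrizing the two arms
        df = make_data(n_subj=10, seed=9, beta=(1.0, 2.0, 0.0, 0.0))
        pl = df[df["arm"] == 0]
        mirrored = pl.assign(arm=1.0, participant_id=pl["participant_id"] + 100)
        sym = pd.concat([pl, mirrored], ignore_index=True)
        fit = fit_lmm(sym)
        assert abs(fit.beta[3]) < 1e-8
        assert fit.p_interaction > 1 - 1e-6

    def test_huge_effect_tiny_noise(self):
        df = make_data(n_subj=20, seed=10, beta=(0.0, 0.0, 0.0, 50.0),
                       sigma_b=0.01, sigma=0.01, phi=0.0)
        fit = fit_lmm(df)
        assert fit.p_interaction < 1e-30

    def test_type1_calibration_when_model_true(self):
        # data generated from the fitted model under the null: rejection rate
        # at alpha=0.05 should be calibrated
        rejections = 0
        n_fits = 400
        for seed in range(n_fits):
            df = make_data(n_subj=30, times=(0.0, 0.25, 0.5, 0.75, 1.0),
                           seed=seed, beta=(1.0, 2.0, 0.0, 0.0), phi=0.3)
            fit = fit_lmm(df)
            if fit.p_interaction < 0.05:
                rejections += 1
        rate = rejections / n_fits
        se = np.sqrt(0.05 * 0.95 / n_fits)
        assert abs(rate - 0.05) < 3 * se + 0.01


class TestCompareAic:
    def test_ar1_preferred_when_phi_large(self):
        df = make_data(n_subj=200, times=tuple(np.linspace(0, 1, 6)), seed=13, phi=0.6)
        f_ar = fit_lmm(df, correlation="ar1")
        f_in = fit_lmm(df, correlation="independent")
        assert dp.compare_aic(f_ar, f_in) is f_ar

    def test_phi_zero_aic_penalty(self):
        df = make_data(n_subj=100, seed=14, phi=0.0)
        f_ar = fit_lmm(df, correlation="ar1")
        f_in = fit_lmm(df, correlation="independent")
        # AR(1) spends one parameter; without true autocorrelation its AIC
        # can beat the independent fit by at most ~0 and lose by up to 2
        assert f_in.aic <= f_ar.aic + 2.0 + 1e-6

    def test_mismatched_data_rejected(self):
        f1 = fit_lmm(make_data(n_subj=10, seed=1))
        f2 = fit_lmm(make_data(n_subj=10, seed=2), correlation="independent")
        with pytest.raises(dp.LmmError):
            dp.compare_aic(f1, f2)


class TestNlmeCrossCheck:
    """Independent oracle: R nlme::lme with corAR1, the reference
    implementation of this model family."""

    def test_matches_nlme(self, tmp_path, small_trial):
        csv = tmp_path / "trial.csv"
        dp.write_trial_csv(small_trial, csv)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(nlme))
            d <- read.csv("{csv}")
            d$arm <- ifelse(d$arm == "treatment", 1, 0)
            m <- lme(value ~ time_years * arm, random = ~1 | participant_id,
                     correlation = corAR1(form = ~1 | participant_id),
                     data = d, method = "ML")
            tt <- summary(m)$tTable
            cat(fixef(m), "\\n")
            cat(coef(m$modelStruct$corStruct, unconstrained = FALSE), "\\n")
            cat(logLik(m), "\\n")
            cat(tt["time_years:arm", "DF"], tt["time_years:arm", "p-value"], "\\n")
        """))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300, check=True,
        )
        lines = [ln for ln in out.stdout.strip().splitlines() if ln.strip()]
        beta_r = np.array([float(x) for x in lines[0].split()])
        phi_r = float(lines[1])
        ll_r = float(lines[2])
        df_r, p_r = (float(x) for x in lines[3].split())

        fit = fit_lmm(small_trial.records, correlation="ar1", method="ml")
        # nlme orders terms (intercept, time, arm, time:arm) like we do
        assert np.allclose(fit.beta, beta_r, rtol=1e-4, atol=1e-6)
        assert fit.phi == pytest.approx(phi_r, abs=0.01)
        assert fit.loglik == pytest.approx(ll_r, abs=0.05)
        assert fit.df_denominator == int(df_r)
        assert fit.p_interaction == pytest.approx(p_r, rel=0.02, abs=1e-4)
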