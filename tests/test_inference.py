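import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aemh_triage.errors import InputError, RankDeficiencyError, UsageError
from aemh_triage.inference import (
    ModelSpec,
    cohen_w,
    covariate_checks,
    fit_clmm,
    fit_lmm,
    intercept_wald,
    lrt,
    manipulation_check,
    run_hypothesis_ladders,
)
from aemh_triage.trial_simulator import DesignConfig, RespondentModel, generate_trial


def one_way_frame(m, k, mu, sigma_b, sigma_e, seed):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(m), k)
    y = mu + rng.normal(0, sigma_b, m)[g] + rng.normal(0, sigma_e, m * k)
    return pd.DataFrame({"participant_id": g + 1, "isr": y}), y, g


def direct_marginal_loglik(y, groups, mu, sigma_b2, sigma_e2):
    """Independent oracle: per-group multivariate-normal marginal likelihood."""
    ll = 0.0
    for gid in np.unique(groups):
        r = y[groups == gid] - mu
        n = len(r)
        V = sigma_e2 * np.eye(n) + sigma_b2 * np.ones((n, n))
        sign, logdet = np.linalg.slogdet(V)
        ll += -0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
    return ll


class TestFitLmm:
    def test_matches_closed_form_balanced_ml_estimators(self):
        """On balanced one-way data the ML fit has a closed form."""
        m, k = 40, 3
        df, y, g = one_way_frame(m, k, 0.7, 1.1, 0.9, seed=5)
        fit = fit_lmm(df, ModelSpec("isr"))

        ybar_i = pd.Series(y).groupby(g).mean().to_numpy()
        ybar = y.mean()
        ssw = float(((y - ybar_i[g]) ** 2).sum())
        ssb = float((k * (ybar_i - ybar) ** 2).sum())
        sigma_e2 = ssw / (m * (k - 1))
        sigma_b2 = max(0.0, (ssb / m - sigma_e2) / k)

        assert fit.beta["intercept"] == pytest.approx(ybar, abs=1e-8)
        assert fit.sigma_e**2 == pytest.approx(sigma_e2, abs=1e-6)
        assert fit.sigma_p**2 == pytest.approx(sigma_b2, abs=1e-6)

    def test_loglik_matches_direct_marginal_evaluation(self):
        df, y, g = one_way_frame(10, 3, 0.2, 0.8, 1.2, seed=8)
        fit = fit_lmm(df, ModelSpec("isr"))
        direct = direct_marginal_loglik(
            y, g, fit.beta["intercept"], fit.sigma_p**2, fit.sigma_e**2
        )
        assert fit.loglik == pytest.approx(direct, abs=1e-6)

    def test_boundary_sigma_p_zero(self):
        df = generate_trial(DesignConfig(), RespondentModel.null(sigma_participant=0.0), seed=3)
        fit = fit_lmm(df, ModelSpec("isr"))
        assert fit.sigma_p == pytest.approx(0.0, abs=0.1)

    def test_duplicated_column_raises_rank_deficiency_naming_term(self, default_trial):
        data = default_trial.copy()
        data["age_copy"] = data["age"]
        with pytest.raises(RankDeficiencyError) as exc:
            fit_lmm(data, ModelSpec("isr", ("intercept", "age", "age_copy")))
        assert exc.value.term == "age_copy"

    def test_nesting_monotonicity_of_loglik(self, default_trial):
        """Adding a fixed term never decreases the ML log-likelihood."""
        ladders = [
            ("intercept",),
            ("intercept", "strategy"),
            ("intercept", "strategy", "situation"),
            ("intercept", "strategy", "situation", "situation:strategy"),
        ]
        lls = [fit_lmm(default_trial, ModelSpec("isr", terms)).loglik for terms in ladders]
        for smaller, larger in zip(lls, lls[1:]):
            assert larger >= smaller - 1e-6


class TestLrt:
    def test_model_against_itself(self, default_trial):
        fit = fit_lmm(default_trial, ModelSpec("isr"))
        res = lrt(fit, fit)
        assert (res.chi2, res.df, res.p) == (0.0, 0, 1.0)

    def test_non_nested_rejected(self, default_trial):
        f1 = fit_lmm(default_trial, ModelSpec("isr", ("intercept", "strategy")))
        f2 = fit_lmm(default_trial, ModelSpec("isr", ("intercept", "situation")))
        with pytest.raises(UsageError):
            lrt(f1, f2)

    def test_different_rows_rejected(self, default_trial):
        f_all = fit_lmm(default_trial, ModelSpec("isr"))
        f_sub = fit_lmm(default_trial, ModelSpec("isr", subset_situations=(1, 2, 5)))
        with pytest.raises(UsageError):
            lrt(f_all, f_sub)

    def test_strong_effect_detected(self):
        model = RespondentModel.null().with_strategy_effect("isr", [0.0, 0.8, -0.8])
        df = generate_trial(DesignConfig(), model, seed=21)
        f0 = fit_lmm(df, ModelSpec("isr"))
        f1 = fit_lmm(df, ModelSpec("isr", ("intercept", "strategy")))
        res = lrt(f0, f1)
        assert res.df == 2
        assert res.p < 0.001


class TestCohenW:
    def test_reported_manipulation_check_effect_sizes(self):
        assert round(cohen_w(142.98, 477), 2) == 0.55
        assert round(cohen_w(184.49, 477), 2) == 0.62

    def test_scale_invariance(self):
        for c in (2.0, 10.0, 0.5):
            assert cohen_w(c * 33.0, int(c * 400)) == pytest.approx(
                cohen_w(33.0, 400), abs=1e-9
            )

    def test_zero_statistic(self):
        assert cohen_w(0.0, 100) == 0.0

    def test_invalid_n(self):
        with pytest.raises(InputError):
            cohen_w(5.0, 0)


class TestFitClmm:
    def test_reduces_to_plain_cumulative_logit_when_no_clustering(self):
        """With sigma_p = 0 in the generator the CLMM must agree with a CLM."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        df = generate_trial(DesignConfig(), RespondentModel.null(sigma_participant=0.0), seed=7)
        levels = ("low", "medium", "high")
        df["scripted"] = df["severity"].map({lv: i - 1 for i, lv in enumerate(levels)})
        fit = fit_clmm(
            df,
            ModelSpec("perceived_severity", ("intercept", "scripted"), family="cumulative_logit"),
        )
        y = df["perceived_severity"].map({lv: i for i, lv in enumerate(levels)})
        clm = OrderedModel(y, df[["scripted"]], distr="logit").fit(method="bfgs", disp=False)
        assert fit.sigma_p == pytest.approx(0.0, abs=0.05)
        assert fit.beta["scripted"] == pytest.approx(clm.params["scripted"], abs=1e-3)
        assert fit.loglik == pytest.approx(clm.llf, abs=1e-3)

    def test_perfect_fidelity_gives_decisive_lrt(self):
        model = replace(RespondentModel(), manipulation_fidelity=1.0)
        df = generate_trial(DesignConfig(n_participants=80), model, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation pushes beta to the boundary
            mc = manipulation_check(df)
        assert mc["severity"]["p"] < 0.001
        assert mc["stance"]["p"] < 0.001

    def test_permuted_scripted_levels_are_rarely_significant(self):
        """Permutation null: the scripted-level LRT keeps its alpha = .01 level."""
        rng = np.random.default_rng(99)
        df = generate_trial(DesignConfig(n_participants=60), seed=17)
        levels = ("low", "medium", "high")
        df["scripted"] = df["severity"].map({lv: i - 1 for i, lv in enumerate(levels)})
        null_fit = fit_clmm(df, ModelSpec("perceived_severity", family="cumulative_logit"))
        rejections = 0
        n_reps = 40
        work = df.copy()
        for _ in range(n_reps):
            work["scripted"] = rng.permutation(df["scripted"].to_numpy())
            alt = fit_clmm(
                work,
                ModelSpec(
                    "perceived_severity", ("intercept", "scripted"), family="cumulative_logit"
                ),
            )
            if lrt(null_fit, alt).p < 0.01 * 1.0:
                rejections += 1
        # P(X > 4 | Binomial(40, .01)) < 1e-4
        assert rejections <= 4

    def test_manipulation_check_reports_effect_sizes(self, default_trial):
        mc = manipulation_check(default_trial)
        for check in ("severity", "stance"):
            assert mc[check]["df"] == 1
            assert mc[check]["w"] == pytest.approx(
                np.sqrt(mc[check]["chi2"] / mc[check]["n"]), abs=1e-12
            )
            assert 0 <= mc[check]["pseudo_r2_mcfadden"] <= 1
            assert 0 <= mc[check]["pseudo_r2_nagelkerke"] <= 1


def discretized_mean(mu, sigma):
    """Expected value of round-and-clamp of N(mu, sigma) on -3..3."""
    vs = np.arange(-3, 4)
    lo = np.where(vs == -3, -np.inf, vs - 0.5)
    hi = np.where(vs == 3, np.inf, vs + 0.5)
    p = stats.norm.cdf(hi, mu, sigma) - stats.norm.cdf(lo, mu, sigma)
    return float((vs * p).sum())


class TestParameterRecovery:
    def test_strategy_contrasts_recovered_over_200_trials(self):
        """Mean estimated contrasts within 2 MC SEs of the generator's truth
        (truth taken on the observed scale, i.e. after discretization)."""
        latent = {"facilitate": 0.05, "persuade": 0.35, "accept_rejection": -0.40}
        model = RespondentModel.null().with_strategy_effect(
            "isr", [latent["facilitate"], latent["persuade"], latent["accept_rejection"]]
        )
        sigma_tot = np.sqrt(model.sigma_participant**2 + model.sigma_residual**2)
        mean_obs = {k: discretized_mean(v, sigma_tot) for k, v in latent.items()}
        truth = {
            "strategy[facilitate]": mean_obs["facilitate"] - mean_obs["accept_rejection"],
            "strategy[persuade]": mean_obs["persuade"] - mean_obs["accept_rejection"],
        }
        estimates = {k: [] for k in truth}
        for i in range(200):
            df = generate_trial(DesignConfig(), model, seed=1000 + i)
            fit = fit_lmm(df, ModelSpec("isr", ("intercept", "strategy")))
            for k in truth:
                estimates[k].append(fit.beta[k])
        for k, vals in estimates.items():
            vals = np.asarray(vals)
            mcse = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - truth[k]) <= 2 * mcse


class TestHypothesisLadders:
    def test_subset_row_counts_match_generator_bookkeeping(self, default_trial):
        report = run_hypothesis_ladders(default_trial, ("h2", "h3", "h4"))
        df = default_trial
        assert report["h2"]["strategy"]["n"] == int(df["situation"].isin([1, 2, 5]).sum())
        assert report["h4"]["icaa"]["strategy"]["n"] == int(
            df["situation"].isin([4, 7, 8]).sum()
        )
        n_h3 = int(
            (df["situation"].isin([3, 6, 9]) & (df["strategy"] == "facilitate")).sum()
        )
        assert report["h3"]["n"] == n_h3

    def test_pairwise_subsets_have_single_df(self, default_trial):
        report = run_hypothesis_ladders(default_trial, ("h2",))
        assert report["h2"]["strategy"]["df"] == 2
        assert report["h2"]["persuade_vs_facilitate"]["df"] == 1
        assert report["h2"]["persuade_vs_accept_rejection"]["df"] == 1

    def test_missing_columns_raise_schema_error(self):
        with pytest.raises(InputError):
            run_hypothesis_ladders(pd.DataFrame({"isr": [1.0]}))

    def test_h3_intercept_test_detects_positive_default_mean(self):
        """Accept-care/facilitate cells with the default grand mean deviate from 0."""
        df = generate_trial(DesignConfig(), RespondentModel(), seed=31)
        report = run_hypothesis_ladders(df, ("h3",))
        assert report["h3"]["intercept"] > 0
        assert report["h3"]["p"] < 0.01
        assert report["h3"]["df"][0] == 1


class TestCovariateChecks:
    def test_constant_covariate_excluded_with_diagnostic(self, default_trial):
        data = default_trial.copy()
        data["site"] = "online"
        report = covariate_checks(data, covariates=("site",), outcomes=("isr",))
        assert report["site"]["excluded"]
        assert "constant" in report["site"]["reason"]

    def test_large_gender_shift_detected_on_fbh(self):
        model = replace(
            RespondentModel.null(),
            gender_fbh_shift={"female": -0.8, "male": 0.8, "other": 0.0},
        )
        df = generate_trial(DesignConfig(), model, seed=41)
        report = covariate_checks(df, covariates=("gender",), outcomes=("fbh",))
        assert report["gender"]["fbh"]["p"] < 0.01

    def test_null_gender_shift_keeps_its_level(self):
        """With no generated gender effect, alpha = .01 rejections stay rare."""
        rejections = 0
        n_reps = 30
        for i in range(n_reps):
            df = generate_trial(DesignConfig(), RespondentModel.null(), seed=5000 + i)
            report = covariate_checks(df, covariates=("gender",), outcomes=("fbh",))
            if report["gender"]["fbh"]["p"] < 0.01:
                rejections += 1
        # P(X > 3 | Binomial(30, .01)) < 3e-4
        assert rejections <= 3


def test_intercept_wald_matches_beta_and_se(default_trial):
    fit = fit_lmm(default_trial, ModelSpec("isr"))
    res = intercept_wald(fit)
    assert res["F"] == pytest.approx((res["intercept"] / res["se"]) ** 2)
    assert res["df"] == (1, fit.n_groups - 1)
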