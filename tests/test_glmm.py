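"""Binomial mixed-model fitting, R² decomposition and group ranking."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from gaitfatigue.glmm_association import (
    associate,
    fit_glmm,
    inverse_frequency_weights,
    r2_nakagawa,
    rank_features,
)
from gaitfatigue.synthetic_data import simulate_association_table


class TestWeights:
    def test_inverse_frequency_identity(self, rng):
        scores = rng.integers(0, 7, size=200)
        w = inverse_frequency_weights(scores)
        _, counts = np.unique(scores, return_counts=True)
        # sum over observations of weight * count(score) equals n
        per_obs_counts = np.array(
            [counts[np.unique(scores).tolist().index(s)] for s in scores])
        assert np.sum(w * per_obs_counts) == pytest.approx(len(scores))

    def test_rare_scores_upweighted(self):
        w = inverse_frequency_weights([0, 0, 0, 6])
        assert w[3] == pytest.approx(1.0) and w[0] == pytest.approx(1 / 3)


class TestFitGlmm:
    def test_recovers_parameters_unweighted(self):
        df = simulate_association_table(80, 25, 0.4, 0.8, rng=3)
        res = fit_glmm(df["x"], df["score"], df["subject_id"],
                       weights=np.ones(len(df)), standardize=False)
        assert res.converged
        assert res.beta == pytest.approx(0.4, abs=0.08)
        assert res.sigma_subject == pytest.approx(0.8, abs=0.2)

    def test_matches_lme4_oracle(self, tmp_path):
        """Independent cross-check of the AGQ fit against R's glmer."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = simulate_association_table(30, 15, 0.3, 0.6, rng=9)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(cbind(score, 6 - score) ~ x + (1 | subject_id),
                       data = d, family = binomial, nAGQ = 10)
            cat(fixef(m)["x"], sqrt(unlist(VarCorr(m))[1]), sep = "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        if out.returncode != 0:
            pytest.skip(f"lme4 unavailable: {out.stderr[-200:]}")
        beta_r, sigma_r = map(float, out.stdout.strip().split("\n"))
        res = fit_glmm(df["x"], df["score"], df["subject_id"],
                       weights=np.ones(len(df)), standardize=False)
        assert res.beta == pytest.approx(beta_r, abs=2e-3)
        assert res.sigma_subject == pytest.approx(sigma_r, abs=2e-2)

    def test_constant_feature_does_not_converge(self):
        df = simulate_association_table(10, 10, 0.0, 0.5, rng=0)
        res = fit_glmm(np.ones(len(df)), df["score"], df["subject_id"])
        assert not res.converged and np.isnan(res.r2_marginal)

    def test_r2_ordering_on_converged_fits(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            df = simulate_association_table(25, 12, 0.2, 0.6, rng=rng)
            res = fit_glmm(df["x"], df["score"], df["subject_id"])
            if res.converged:
                assert 0 <= res.r2_marginal <= res.r2_conditional <= 1

    def test_no_subject_effects_conditional_near_marginal(self):
        """Without generator subject effects the two R² coincide (unit
        weights isolate the variance decomposition; inverse-frequency
        weighting itself manufactures apparent between-subject variance)."""
        df = simulate_association_table(40, 20, 0.3, 0.0, rng=5)
        res = fit_glmm(df["x"], df["score"], df["subject_id"],
                       weights=np.ones(len(df)))
        assert res.converged
        assert res.r2_conditional - res.r2_marginal < 0.02

    def test_r2_close_to_plugin_value(self):
        """Estimated R² tracks the closed-form plug-in from the generator
        variances (unit weights isolate the R² computation)."""
        beta, sd_a = 0.5, 0.7
        df = simulate_association_table(120, 30, beta, sd_a, rng=11)
        res = fit_glmm(df["x"], df["score"], df["subject_id"],
                       weights=np.ones(len(df)), standardize=False)
        denom = beta ** 2 + sd_a ** 2 + np.pi ** 2 / 3
        assert res.converged
        assert res.r2_marginal == pytest.approx(beta ** 2 / denom, abs=0.02)
        assert res.r2_conditional == pytest.approx(
            (beta ** 2 + sd_a ** 2) / denom, abs=0.04)


class TestR2Nakagawa:
    def test_zero_slope_marginal_zero(self):
        x = np.random.default_rng(0).normal(size=100)
        r2m, r2c = r2_nakagawa(0.0, x, sigma_subject=0.8)
        assert r2m == 0.0 and r2c > 0.0

    def test_zero_random_variance_equal(self):
        x = np.random.default_rng(0).normal(size=100)
        r2m, r2c = r2_nakagawa(0.5, x, sigma_subject=0.0)
        assert r2m == pytest.approx(r2c)


class TestRanking:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["group", "statistic", "r2_conditional",
                                           "p_value", "converged"])

    def test_all_equal_none_significant_ties(self):
        res = self._results([
            ("a", "mean", 0.1, 0.5, True),
            ("b", "mean", 0.1, 0.5, True),
        ])
        out = rank_features(res)
        assert out["mean_r2"].nunique() == 1

    def test_double_weighting_of_significant_entries(self):
        res = self._results([
            ("a", "mean", 0.3, 0.01, True), ("a", "sd", 0.1, 0.5, True),
            ("b", "mean", 0.3, 0.50, True), ("b", "sd", 0.1, 0.5, True),
        ])
        out = rank_features(res).set_index("group")
        # a: (2*0.3 + 0.1)/3, b: (0.3 + 0.1)/2
        assert out.loc["a", "mean_r2"] == pytest.approx(0.7 / 3)
        assert out.loc["b", "mean_r2"] == pytest.approx(0.2)
        assert out.loc["a", "rank"] < out.loc["b", "rank"]

    def test_coupled_feature_group_ranks_first(self):
        """Only one coupled feature: its group tops the ranking in most seeds."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            df = simulate_association_table(30, 14, 0.5, 0.5, rng=rng)
            df["macro__coupled__x__mean"] = df["x"]
            df["macro__noise__a__mean"] = rng.standard_normal(len(df))
            df["macro__noise__b__mean"] = rng.standard_normal(len(df))
            res = associate(df, ["macro__coupled__x__mean",
                                 "macro__noise__a__mean",
                                 "macro__noise__b__mean"], label="score")
            ranked = rank_features(res)
            if ranked.iloc[0]["group"] == "coupled":
                wins += 1
        assert wins >= 0.9 * n_seeds
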