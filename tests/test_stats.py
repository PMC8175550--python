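"""Cohort statistics: size matching, paired-eye mixed model, Welch's ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from zfo import synthetic as syn
from zfo.stats import (
    crosssectional_report,
    fit_random_intercept_lmm,
    size_match_controls,
    welch_anova,
)


def cohort(**kw):
    return syn.generate_cohort(syn.CohortSpec(**kw))


class TestSizeMatching:
    def test_all_wt_at_mutant_mean_kept(self):
        df = cohort(body_length_sd_mm=0.0)
        out = size_match_controls(df)
        pd.testing.assert_frame_equal(out, df)

    def test_ten_percent_band_boundaries(self):
        df = cohort(body_length_sd_mm=0.0, body_length_mean_mm=20.0, seed=1)
        # plant two WT fish just inside / outside the band around the 20 mm mean
        df.loc[df.fish_id == "WT_000", "body_length_mm"] = 21.9
        df.loc[df.fish_id == "WT_001", "body_length_mm"] = 22.1
        out = size_match_controls(df)
        kept = set(out.loc[out.genotype == "WT", "fish_id"])
        assert "WT_000" in kept
        assert "WT_001" not in kept

    def test_fish_level_filtering_keeps_or_drops_both_eyes(self):
        df = cohort(body_length_sd_mm=2.0, seed=2)
        out = size_match_controls(df)
        assert (out.groupby("fish_id").size() == 2).all()

    def test_idempotent_when_all_inside_band(self):
        df = cohort(body_length_sd_mm=0.5, seed=3)
        once = size_match_controls(df)
        twice = size_match_controls(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_mutant_group_rejected(self):
        df = cohort(seed=4)
        with pytest.raises(ValueError):
            size_match_controls(df[df.genotype == "WT"])


class TestMixedModel:
    def test_noiseless_estimate_is_exact_group_difference(self):
        df = cohort(between_fish_sd=0.0, residual_sd=0.0, genotype_effect=-47.0)
        fit = fit_random_intercept_lmm(df)
        assert fit.beta1 == pytest.approx(-47.0, abs=1e-9)

    def test_balanced_design_matches_closed_form_oracle(self):
        # balanced two-group paired-eye design: the GLS fixed effect equals the
        # raw group-mean difference, and REML variance components equal the
        # one-way ANOVA moment estimators
        df = cohort(seed=5)
        fit = fit_random_intercept_lmm(df)
        y = df["value"].to_numpy()
        mut = df.genotype.to_numpy() == "mutant"
        oracle_beta1 = y[mut].mean() - y[~mut].mean()
        assert fit.beta1 == pytest.approx(oracle_beta1, abs=1e-5)
        # moment estimators from fish means (after removing genotype means)
        centered = df.assign(
            c=y - np.where(mut, y[mut].mean(), y[~mut].mean())
        )
        fish_means = centered.groupby("fish_id")["c"].mean()
        n_fish = fish_means.size
        ms_within = float(
            centered.groupby("fish_id")["c"].var(ddof=1).mean()
        ) / 1.0
        ms_between = float(fish_means.var(ddof=1) * 2)  # 2 eyes per fish
        sigma_e2 = ms_within
        sigma_u2 = max((ms_between - ms_within) / 2.0, 0.0)
        assert fit.sigma_e**2 == pytest.approx(sigma_e2, rel=0.05)
        assert fit.sigma_u**2 == pytest.approx(sigma_u2, rel=0.10)

    def test_reduces_to_ols_without_between_fish_variance(self):
        df = cohort(between_fish_sd=0.0, residual_sd=10.0, seed=6)
        fit = fit_random_intercept_lmm(df)
        import statsmodels.formula.api as smf

        ols = smf.ols("value ~ genotype", df).fit()
        term = [t for t in ols.params.index if t.startswith("genotype")][0]
        assert fit.beta1 == pytest.approx(float(ols.params[term]), abs=0.5)

    def test_single_genotype_rejected(self):
        df = cohort(seed=7)
        with pytest.raises(ValueError):
            fit_random_intercept_lmm(df[df.genotype == "WT"])

    def test_effect_recovered_on_single_realistic_cohort(self):
        df = cohort(genotype_effect=-47.0, seed=8)
        fit = fit_random_intercept_lmm(df)
        assert fit.beta1 == pytest.approx(-47.0, abs=4 * fit.se)
        assert fit.p_value < 0.001


class TestWelchAnova:
    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = welch_anova([g, list(g)])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equal_welch_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2.5, 9)
        res = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_three_groups_against_textbook_formula(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, s, n) for m, s, n in
                  [(0, 1, 10), (0.5, 2, 14), (1.2, 0.5, 8)]]
        res = welch_anova(groups)
        # independent hand computation of Welch's F
        w = np.array([g.size / np.var(g, ddof=1) for g in groups])
        means = np.array([g.mean() for g in groups])
        grand = np.sum(w * means) / w.sum()
        k = len(groups)
        num = np.sum(w * (means - grand) ** 2) / (k - 1)
        h = np.sum(
            [(1 - wi / w.sum()) ** 2 / (g.size - 1) for wi, g in zip(w, groups)]
        )
        den = 1 + 2 * (k - 2) / (k**2 - 1) * h
        assert res.f_statistic == pytest.approx(num / den, rel=1e-9)
        assert res.df_den == pytest.approx((k**2 - 1) / (3 * h), rel=1e-9)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])


class TestCrossSectional:
    def test_single_age_matches_direct_fit(self):
        df = cohort(seed=9)
        rep = crosssectional_report(df)
        direct = fit_random_intercept_lmm(size_match_controls(df))
        assert rep.shape[0] == 1
        assert rep.loc[0, "beta1"] == pytest.approx(direct.beta1, abs=1e-9)

    def test_three_ages_recover_designed_effects(self):
        designs = {"1.5 mpf": -47.0, "2 mpf": -48.0, "3 mpf": -43.0}
        frames = [
            syn.generate_cohort(
                syn.CohortSpec(age=age, genotype_effect=eff, seed=10 + i)
            )
            for i, (age, eff) in enumerate(designs.items())
        ]
        rep = crosssectional_report(pd.concat(frames, ignore_index=True))
        for _, row in rep.iterrows():
            assert row["beta1"] == pytest.approx(
                designs[row["age"]], abs=4 * row["se"]
            )

    def test_wt_only_age_flagged_without_breaking_others(self):
        good = cohort(age="2 mpf", seed=13)
        bad = cohort(age="3 mpf", seed=14)
        bad = bad[bad.genotype == "WT"]
        rep = crosssectional_report(pd.concat([good, bad], ignore_index=True))
        rep = rep.set_index("age")
        assert rep.loc["2 mpf", "error"] == ""
        assert rep.loc["3 mpf", "error"] != ""
        assert np.isnan(rep.loc["3 mpf", "beta1"])
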