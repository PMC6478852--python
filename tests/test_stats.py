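"""Frequentist and Bayesian inference: paired t, JZS Bayes factors,
repeated-measures ANOVA, exact binomial, dose regression."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from gainloss.stats import (
    BayesConfig,
    DegenerateInputError,
    binomial_two_sided,
    dose_response,
    jzs_bf01,
    jzs_bf10,
    paired_t,
    posterior_effect,
    rm_anova,
)


class TestPairedT:
    def test_three_pair_closed_form(self):
        # differences 1, 2, 3: mean 2, sd 1, t = 2*sqrt(3)
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * math.sqrt(3), abs=1e-10)
        assert res.df == 2
        assert res.cohens_d == pytest.approx(res.t / math.sqrt(3), abs=1e-12)

    def test_effect_size_from_t_and_n(self):
        # d = t / sqrt(n) for a paired design
        assert 0.906 / math.sqrt(31) == pytest.approx(0.163, abs=5e-4)

    def test_ci_contains_mean_difference(self, rng):
        x = rng.normal(10, 2, 25)
        y = rng.normal(9, 2, 25)
        res = paired_t(x, y)
        assert res.ci_low < np.mean(x - y) < res.ci_high

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0], [0.0])
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])  # constant difference

    def test_incomplete_pairs_dropped(self, rng):
        x = np.array([1.0, 2.0, np.nan, 4.0, 2.5])
        y = np.array([0.5, 1.0, 2.0, 1.0, np.nan])
        assert paired_t(x, y).n == 3


class TestJzsBayesFactor:
    def test_published_values_from_t_and_n(self):
        assert jzs_bf01(0.906, 31, 0.707) == pytest.approx(3.581, abs=5e-3)
        assert jzs_bf01(1.771, 31, 0.707) == pytest.approx(1.301, abs=5e-3)

    def test_orientation_identity(self):
        for t in (0.0, 0.8, 2.5):
            assert jzs_bf01(t, 31) * jzs_bf10(t, 31) == pytest.approx(1.0, abs=1e-10)

    def test_monotone_decreasing_in_t_magnitude(self):
        vals = [jzs_bf01(t, 31) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_sign_symmetric(self):
        assert jzs_bf01(-1.771, 31) == pytest.approx(jzs_bf01(1.771, 31), rel=1e-8)

    def test_null_point_favours_null(self):
        assert jzs_bf01(0.0, 31) > 1

    def test_agrees_with_independent_implementation(self):
        # pingouin's closed-form JZS BF10 as the cross-check
        for t, n in [(0.906, 31), (1.771, 31), (2.5, 20)]:
            assert jzs_bf10(t, n, 0.707) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707)), rel=1e-4)

    def test_wider_prior_changes_bf(self):
        assert jzs_bf01(0.906, 31, 1.0) != pytest.approx(jzs_bf01(0.906, 31, 0.707), rel=1e-3)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf01(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bf01(1.0, 31, prior_scale=0.0)


class TestPosteriorEffect:
    def test_zero_t_gives_symmetric_posterior(self):
        med, lo, hi = posterior_effect(0.0, 31)
        assert med == pytest.approx(0.0, abs=1e-10)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_published_posterior_summary(self):
        med, lo, hi = posterior_effect(0.906, 31)
        assert med == pytest.approx(0.148, abs=5e-3)
        assert lo == pytest.approx(-0.186, abs=1e-2)
        assert hi == pytest.approx(0.482, abs=1e-2)

    def test_grid_refinement_stable(self):
        m1, *_ = posterior_effect(0.906, 31, grid_points=10001)
        m2, *_ = posterior_effect(0.906, 31, grid_points=20001)
        assert abs(m1 - m2) < 1e-4

    def test_prior_washout_towards_mle(self):
        # large n at fixed observed effect size: median -> d = t/sqrt(n)
        n = 2000
        d = 0.25
        t = d * math.sqrt(n)
        med, *_ = posterior_effect(t, n)
        assert med == pytest.approx(d, abs=0.01)


def _long_table(rng, n_sub=30, times=("t0", "t30", "t24h"), drugs=("drug", "placebo")):
    rows = []
    for s in range(n_sub):
        base = rng.normal(70, 8)
        for tm in times:
            for dr in drugs:
                rows.append({"subject": f"S{s:02d}", "time": tm, "drug": dr,
                             "y": base + rng.normal(0, 5)})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_way_design_dfs(self, rng):
        res = rm_anova(_long_table(rng), dv="y", within=["time", "drug"], subject="subject")
        by = {e.source: e for e in res.effects}
        assert (by["time"].df1, by["time"].df2) == (2, 58)
        assert (by["drug"].df1, by["drug"].df2) == (1, 29)
        assert (by["time * drug"].df1, by["time * drug"].df2) == (2, 58)
        for e in res.effects:
            assert 0.0 <= e.partial_eta_sq <= 1.0

    def test_duplicated_condition_gives_zero_f(self, rng):
        df = _long_table(rng, times=("t0",))
        wide = df.pivot(index="subject", columns="drug", values="y")
        dup = df.copy()
        dup["y"] = dup["subject"].map(wide["drug"])  # identical across drug levels
        res = rm_anova(dup, dv="y", within=["drug"], subject="subject")
        assert res["drug"].F == pytest.approx(0.0, abs=1e-10)

    def test_two_level_factor_epsilon_is_one(self, rng):
        df = _long_table(rng, times=("t0",))
        res = rm_anova(df, dv="y", within=["drug"], subject="subject")
        assert res["drug"].gg_epsilon == 1.0
        assert res["drug"].gg_applied is False

    def test_epsilon_bounds_for_three_levels(self, rng):
        df = _long_table(rng, drugs=("drug",)).drop(columns="drug")
        df["drug"] = "x"
        res = rm_anova(df, dv="y", within=["time"], subject="subject")
        eps = res["time"].gg_epsilon
        assert 1 / (3 - 1) <= eps <= 1.0
        assert res["time"].mauchly_p is not None

    def test_f_equals_t_squared_on_2x2(self, rng):
        df = _long_table(rng, times=("t0", "t24h"))
        res = rm_anova(df, dv="y", within=["time", "drug"], subject="subject")
        wide = df.pivot_table(index="subject", columns="time", values="y")
        from gainloss.stats import paired_t
        t_res = paired_t(wide["t0"], wide["t24h"])
        assert res["time"].F == pytest.approx(t_res.t ** 2, rel=1e-8)

    def test_incomplete_subjects_dropped_listwise(self, rng):
        df = _long_table(rng)
        df = df[~((df.subject == "S00") & (df.time == "t24h"))]  # one incomplete subject
        res = rm_anova(df, dv="y", within=["time", "drug"], subject="subject")
        assert res["drug"].df2 == 28  # 29 complete subjects


class TestBinomial:
    def test_extreme_count_small_n(self):
        assert binomial_two_sided(3, 3, 0.5, method="minlike") == pytest.approx(0.25)
        assert binomial_two_sided(3, 3, 0.5, method="doubling") == pytest.approx(0.25)

    def test_observed_equal_to_null_gives_one(self):
        assert binomial_two_sided(2, 4, 0.5) == pytest.approx(1.0)

    def test_blinding_guess_rate(self):
        # 17 correct of 29: both exact conventions near 0.458
        assert binomial_two_sided(17, 29, 0.5, method="minlike") == pytest.approx(0.458, abs=5e-3)
        assert binomial_two_sided(17, 29, 0.5, method="doubling") == pytest.approx(0.458, abs=5e-3)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            binomial_two_sided(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_two_sided(1, 3, 1.0)


class TestDoseResponse:
    def test_constant_outcome_zero_r2(self):
        res = dose_response([1.5, 2.0, 2.5, 1.8], [3.0, 3.0, 3.0, 3.0], degree=1)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        x = np.array([1.0, 1.5, 2.0, 2.5])
        res = dose_response(x, 2 * x, degree=1)
        assert res.r_squared == pytest.approx(1.0)

    def test_quadratic_captures_curvature(self):
        x = np.linspace(1, 3, 12)
        y = (x - 2) ** 2
        assert dose_response(x, y, degree=2).r_squared == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dose_response([1.0, 2.0], [1.0, 2.0], degree=1)

    def test_null_simulation_p_roughly_uniform(self, rng):
        # cheap calibration check: null p-values should not pile up near 0
        ps = []
        for _ in range(300):
            x = rng.normal(2, 0.3, 31)
            y = rng.normal(0, 5, 31)
            ps.append(dose_response(x, y, degree=1).p)
        assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.10
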