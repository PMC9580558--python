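"""Mixed-model machinery: sex residualization, REML, ANOVA, Tukey HSD,
responder contrasts, and the fixed-effects cross-site ANOVA."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccsens import (
    anova_fixed,
    anova_table,
    classify_responders,
    fit_lmm,
    residualize_sex,
    responder_count,
    simulate_cohort,
    tukey_hsd,
)
from ccsens.lmm import RankDeficiencyError, _reml_deviance
from ccsens.simulate import SimulationConfig

from conftest import one_way_frame


class TestResidualizeSex:
    def test_perfectly_explained_by_sex(self):
        y = np.array([10.0, 10.0, 20.0, 20.0])
        sex = np.array(["F", "F", "M", "M"])
        assert np.allclose(residualize_sex(y, sex), 0.0)

    def test_hand_ols_per_sex_mean(self):
        res = residualize_sex(np.array([1.0, 2, 3, 4]), np.array(["F", "F", "M", "M"]))
        assert np.allclose(res, [-0.5, 0.5, -0.5, 0.5])

    def test_no_sex_effect_reduces_to_grand_centering(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 1, 200)
        sex = np.array(["F", "M"] * 100)
        res = residualize_sex(y, sex)
        # within-sex centering; with no true sex effect both means ~ grand mean
        assert abs(res.mean()) < 1e-12
        assert np.allclose(np.sort(res), np.sort(y - y.mean()), atol=0.5)

    def test_sums_to_zero_within_each_sex(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 101)
        sex = rng.choice(["F", "M"], 101)
        res = residualize_sex(y, sex)
        for s in ("F", "M"):
            assert abs(res[sex == s].sum()) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 50)
        sex = np.array(["F", "M"] * 25)
        once = residualize_sex(y, sex)
        assert np.allclose(residualize_sex(once, sex), once, atol=1e-12)

    def test_single_sex_mean_centers(self):
        y = np.array([1.0, 2.0, 3.0])
        res = residualize_sex(y, np.array(["F", "F", "F"]))
        assert np.allclose(res, y - 2.0)

    def test_missing_values_stay_missing(self):
        y = np.array([1.0, np.nan, 3.0, 4.0])
        res = residualize_sex(y, np.array(["F", "F", "M", "M"]))
        assert np.isnan(res[1]) and np.isfinite(res[[0, 2, 3]]).all()


class TestREML:
    def test_balanced_one_way_equals_method_of_moments(self):
        rng = np.random.default_rng(2)
        a, n = 8, 6
        y = np.repeat(rng.normal(0, 2, a), n) + rng.normal(0, 1, a * n)
        fit = fit_lmm(one_way_frame(y, a, n), response="y", fixed=(), group="strain")
        gm = y.reshape(a, n).mean(1)
        msb = n * ((gm - y.mean()) ** 2).sum() / (a - 1)
        msw = ((y.reshape(a, n) - gm[:, None]) ** 2).sum() / (a * n - a)
        assert fit.var_resid == pytest.approx(msw, abs=1e-6)
        assert fit.var_mouse == pytest.approx((msb - msw) / n, abs=1e-6)

    def test_boundary_when_between_variance_small(self):
        rng = np.random.default_rng(3)
        a, n = 6, 8
        y = rng.normal(0, 1, a * n)  # no group component at all
        fit = fit_lmm(one_way_frame(y, a, n), response="y", fixed=(), group="strain")
        gm = y.reshape(a, n).mean(1)
        msb = n * ((gm - y.mean()) ** 2).sum() / (a - 1)
        msw = ((y.reshape(a, n) - gm[:, None]) ** 2).sum() / (a * n - a)
        if msb < msw:  # MoM would go negative -> REML sits on the boundary
            assert fit.boundary and fit.var_mouse == 0.0

    def test_objective_beats_grid(self, small_cohort):
        table, _, _ = small_cohort
        df = table.records.copy()
        df["resid"] = residualize_sex(df["distance"], df["sex"])
        fit = fit_lmm(df, response="resid")
        dev_hat = _reml_deviance(fit._blocks, fit.ratio, fit.n_obs)[0]
        for lam in np.logspace(-6, 6, 64):
            assert dev_hat <= _reml_deviance(fit._blocks, lam, fit.n_obs)[0] + 1e-6

    def test_boundary_fit_matches_ols_closed_form(self):
        # independent errors: lam = 0 fit must reproduce OLS cell means
        rng = np.random.default_rng(4)
        cfg = SimulationConfig(n_strains=3, mice_per_strain_per_arm=3,
                               var_strain=0.0, var_strain_slope=0.0,
                               var_mouse=1e-9, var_resid=1.0e6,
                               sex_effect=0.0, site_effect=0.0, seed=8)
        table, _ = simulate_cohort(cfg)
        df = table.records
        fit = fit_lmm(df, response="distance")
        if fit.boundary:
            cell_means = df.groupby(["day", "treatment_group", "strain"])["distance"].mean()
            for cell, i in zip(fit.cells, range(len(fit.cells))):
                assert fit.beta[i] == pytest.approx(cell_means.loc[cell], abs=1e-8)

    def test_degenerate_zero_variance_flagged(self):
        df = pd.DataFrame({
            "y": [5.0] * 12,
            "day": [1, 2, 3] * 4,
            "treatment_group": ["cocaine"] * 6 + ["saline"] * 6,
            "strain": ["A"] * 12,
            "mouse_id": np.repeat([f"m{i}" for i in range(4)], 3),
        })
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_lmm(df, response="y", fixed=("day", "treatment_group", "strain"))
        assert fit.degenerate
        assert np.allclose(fit.beta[fit.observed], 5.0)

    def test_parameter_recovery_with_known_components(self):
        # 100 mice x 9 days at known variance components
        cfg = SimulationConfig(n_strains=10, mice_per_strain_per_arm=5,
                               var_strain=0.0, var_strain_slope=0.0,
                               var_mouse=4.0, var_resid=1.0, grand_mean=100.0,
                               sex_effect=0.0, site_effect=0.0,
                               cocaine_acute_effect=3.0, ramp=(0.0,) * 5,
                               conditioned_effect=0.0, day_effects=(0.0,) * 9,
                               seed=10)
        table, _ = simulate_cohort(cfg)
        fit = fit_lmm(table.records, response="distance")
        # REML sampling SD of s2_mouse ~ sqrt(2/n_mice)*(s2m + s2e/9) ~ 0.63
        assert fit.var_mouse == pytest.approx(4.0, abs=3 * 0.65)
        assert fit.var_resid == pytest.approx(1.0, abs=3 * 0.06)

    def test_mouse_level_factor_varying_within_mouse_rejected(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 4.0],
            "day": [1, 2, 1, 2],
            "treatment_group": ["cocaine", "saline", "cocaine", "cocaine"],
            "strain": ["A", "A", "A", "A"],
            "mouse_id": ["m1", "m1", "m2", "m2"],
        })
        with pytest.raises(ValueError, match="varies within"):
            fit_lmm(df, response="y", fixed=("day", "treatment_group", "strain"))

    def test_saturated_design_rejected(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0],
            "day": [1, 1],
            "mouse_id": ["m1", "m2"],
            "strain": ["A", "B"],
        })
        with pytest.raises(RankDeficiencyError):
            fit_lmm(df, response="y", fixed=("day", "strain"))


class TestAnova:
    def test_single_factor_balanced_equals_classical_f(self):
        # 3 groups x 4 mice, one obs per mouse: classical one-way ANOVA
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 12) + np.repeat([0.0, 1.0, 2.0], 4)
        df = pd.DataFrame({
            "y": y,
            "strain": np.repeat(["A", "B", "C"], 4),
            "mouse_id": np.repeat([f"m{i}" for i in range(6)], 2),
        })
        # mice nested in strain, 2 obs per mouse
        fit = fit_lmm(df, response="y", fixed=("strain",))
        row = anova_table(fit)[0]
        f_sm, p_sm = stats.f_oneway(y[:4], y[4:8], y[8:])
        if fit.boundary:  # classical one-way only valid without mouse component
            assert row.f_value == pytest.approx(f_sm, rel=1e-6)
            assert row.df_den == pytest.approx(9)

    def test_satterthwaite_collapses_to_residual_df_at_boundary(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 40),
            "day": [1, 2] * 20,
            "mouse_id": np.repeat([f"m{i}" for i in range(20)], 2),
            "strain": ["A"] * 40,
        })
        fit = fit_lmm(df, response="y", fixed=("day",))
        if fit.boundary:
            row = anova_table(fit)[0]
            assert row.df_den == pytest.approx(fit.n_obs - 2)

    def test_empty_cell_raises_rank_error(self):
        df = pd.DataFrame({
            "y": np.arange(12.0),
            "day": [1, 2] * 6,
            "treatment_group": ["cocaine"] * 6 + ["saline"] * 6,
            "strain": ["A"] * 6 + ["B"] * 6,  # no cocaine-B or saline-A cells
            "mouse_id": np.repeat([f"m{i}" for i in range(6)], 2),
        })
        fit = fit_lmm(df, response="y", fixed=("day", "treatment_group", "strain"))
        with pytest.raises(RankDeficiencyError, match="empty cells"):
            anova_table(fit)

    def test_three_way_terms_present(self, small_cohort):
        table, _, _ = small_cohort
        df = table.records.copy()
        df["resid"] = residualize_sex(df["distance"], df["sex"])
        fit = fit_lmm(df, response="resid")
        rows = anova_table(fit)
        terms = {r.term for r in rows}
        assert terms == {
            "day", "treatment_group", "strain", "day:treatment_group",
            "day:strain", "treatment_group:strain", "day:treatment_group:strain",
        }
        for r in rows:
            assert r.f_value >= 0 and 0 <= r.p_value <= 1
            assert r.df_num > 0 and r.df_den > 0
        # strong simulated treatment effect must be detected
        tre = next(r for r in rows if r.term == "treatment_group")
        assert tre.p_value < 1e-6


class TestTukey:
    def test_k2_reduces_to_t_test(self):
        means = np.array([1.0, 2.5])
        se = np.full((2, 2), 0.8)
        df = 17.0
        out = tukey_hsd(means, se, df)
        t = abs(means[0] - means[1]) / 0.8
        p_t = 2 * stats.t.sf(t, df)
        assert out["p_tukey"].iloc[0] == pytest.approx(p_t, abs=1e-8)

    def test_identical_means_give_p_one(self):
        means = np.array([3.0, 3.0, 3.0])
        se = np.full((3, 3), 1.0)
        out = tukey_hsd(means, se, 12.0)
        assert np.allclose(out["p_tukey"], 1.0, atol=1e-8)

    def test_monotone_in_difference(self):
        se = np.full((2, 2), 1.0)
        ps = [
            tukey_hsd(np.array([0.0, d]), se, 10.0)["p_tukey"].iloc[0]
            for d in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_studentized_range_cdf_vs_monte_carlo(self):
        # P(Q_{3,12} > 3.77) by simulation: max-min of 3 normals over
        # sqrt(chi2_12 / 12), 10^6 draws
        rng = np.random.default_rng(123)
        z = rng.normal(size=(1_000_000, 3))
        s = np.sqrt(rng.chisquare(12, size=1_000_000) / 12)
        q = (z.max(axis=1) - z.min(axis=1)) / s
        mc = (q > 3.77).mean()
        exact = stats.studentized_range.sf(3.77, 3, 12)
        assert exact == pytest.approx(mc, abs=1e-3)

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            tukey_hsd(np.array([1.0, 2.0]), np.full((2, 2), 1.0), 0.0)


class TestResponders:
    def test_strong_effect_detected_null_strains_not(self):
        cfg = SimulationConfig(n_strains=5, mice_per_strain_per_arm=8,
                               var_strain=0.0, var_strain_slope=0.0,
                               var_mouse=1.0, var_resid=1.0, grand_mean=100.0,
                               sex_effect=0.0, site_effect=0.0,
                               cocaine_acute_effect=10.0, ramp=(0.0,) * 5,
                               conditioned_effect=0.0, day_effects=(0.0,) * 9,
                               seed=77)
        table, _ = simulate_cohort(cfg)
        fit = fit_lmm(table.records, response="distance")
        res = classify_responders(fit)
        # acute effect 10 sd on 6 of 9 days -> marginal shift ~6.7 sd: all hit
        assert responder_count(res) == 5
        for r in res:
            assert r.p_tukey >= r.p_unadjusted
            assert r.responder == (r.p_tukey < 0.05 and r.estimate > 0)

    def test_strain_in_one_arm_is_inestimable(self):
        cfg = SimulationConfig(n_strains=3, mice_per_strain_per_arm=4, seed=21)
        table, _ = simulate_cohort(cfg)
        df = table.records
        df = df[~((df["strain"] == "SIM002") & (df["treatment_group"] == "saline"))]
        fit = fit_lmm(df, response="distance")
        res = classify_responders(fit)
        flags = {r.strain: r.estimable for r in res}
        assert flags["SIM002"] is False
        assert flags["SIM001"] and flags["SIM003"]
        assert all(r.estimable for r in res if r.strain != "SIM002")
        assert responder_count(res) <= 2


class TestAnovaFixed:
    def test_balanced_two_by_two_matches_hand_sums_of_squares(self):
        # strain x sex, 2 obs per cell; hand Type III = classical balanced ANOVA
        df = pd.DataFrame({
            "y": [10.0, 12, 20, 22, 30, 32, 48, 50],
            "strain": ["A", "A", "A", "A", "B", "B", "B", "B"],
            "sex": ["F", "F", "M", "M", "F", "F", "M", "M"],
        })
        rows = {r.term: r for r in anova_fixed(df, "y", factors=("strain", "sex"))}
        cell = df.groupby(["strain", "sex"])["y"].mean()
        gm = df["y"].mean()
        ss_strain = 4 * ((cell.groupby("strain").mean() - gm) ** 2).sum()
        ss_sex = 4 * ((cell.groupby("sex").mean() - gm) ** 2).sum()
        ss_int = 2 * ((cell - cell.groupby("strain").mean() - cell.groupby("sex").mean() + gm) ** 2).sum()
        ss_err = ((df["y"] - df.merge(cell.rename("m"), on=["strain", "sex"])["m"]) ** 2).sum()
        ms_err = ss_err / 4
        assert rows["strain"].f_value == pytest.approx(ss_strain / ms_err, rel=1e-9)
        assert rows["sex"].f_value == pytest.approx(ss_sex / ms_err, rel=1e-9)
        assert rows["strain:sex"].f_value == pytest.approx(ss_int / ms_err, rel=1e-9)
        assert rows["strain"].df_den == 4

    def test_matches_statsmodels_type3_on_unbalanced_data(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(9)
        n = 60
        df = pd.DataFrame({
            "strain": rng.choice(["A", "B", "C"], n),
            "sex": rng.choice(["F", "M"], n),
            "site": rng.choice(["JAX", "UNC"], n),
        })
        df["y"] = (
            rng.normal(0, 1, n)
            + (df["strain"] == "B") * 1.0
            + (df["sex"] == "F") * 0.5
        )
        ours = {r.term: r for r in anova_fixed(df, "y")}
        m = smf.ols(
            "y ~ C(strain, Sum) * C(sex, Sum) + C(strain, Sum) * C(site, Sum)"
            " + C(sex, Sum) * C(site, Sum)",
            df,
        ).fit()
        theirs = sm.stats.anova_lm(m, typ=3)
        name_map = {
            "strain": "C(strain, Sum)", "sex": "C(sex, Sum)", "site": "C(site, Sum)",
            "strain:sex": "C(strain, Sum):C(sex, Sum)",
            "strain:site": "C(strain, Sum):C(site, Sum)",
            "sex:site": "C(sex, Sum):C(site, Sum)",
        }
        for term, smname in name_map.items():
            assert ours[term].f_value == pytest.approx(theirs.loc[smname, "F"], rel=1e-6)

    def test_single_site_term_dropped_with_note(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 24),
            "strain": rng.choice(["A", "B"], 24),
            "sex": rng.choice(["F", "M"], 24),
            "site": ["JAX"] * 24,
        })
        rows = anova_fixed(df, "y")
        site_row = next(r for r in rows if r.term == "site")
        assert "dropped" in site_row.note
        assert np.isnan(site_row.f_value)
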