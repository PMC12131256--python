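import math

import numpy as np
import pandas as pd
import pytest

from probemech.groups import assign_scheme
from probemech.stats import (
    ModelSpec,
    StatsError,
    anova_type2,
    build_analysis_frame,
    emm_contrasts,
    fit_group_model,
    percent_rigidity_difference,
)
from probemech.synth import SyntheticConfig, generate_cohort


def analysis_frame(seed=21, scheme_name="tool_source", **cfg_kw):
    cfg = SyntheticConfig(seed=seed, **cfg_kw)
    records, truth = generate_cohort(cfg)
    for r in records:
        t = truth[r.sample_id]
        r.EI, r.E, r.qc_pass = t.EI_true, t.E_true, True
    scheme = assign_scheme(records, scheme_name)
    return build_analysis_frame(records, scheme)


class TestModelSpec:
    def test_log_I_only_for_EI(self):
        assert ModelSpec("log_EI", "tool_source").with_log_I
        assert not ModelSpec("log_E", "tool_source").with_log_I

    def test_bad_response(self):
        with pytest.raises(StatsError):
            ModelSpec("EI", "tool_source")


class TestFitGroupModel:
    def test_fits_and_reports(self):
        frame = analysis_frame()
        res = fit_group_model(frame, ModelSpec("log_EI", "tool_source"))
        assert set(res.var_components) == {"plant_var", "residual_var"}
        assert res.var_components["residual_var"] > 0
        assert "log_I" in res.fixed_effects
        assert res.f_table is not None and len(res.f_table) == 2

    def test_log_E_model_has_no_covariate(self):
        frame = analysis_frame()
        res = fit_group_model(frame, ModelSpec("log_E", "tool_source"))
        assert "log_I" not in res.fixed_effects
        assert list(res.f_table["term"]) == ["tool_source"]

    def test_single_level_errors(self):
        frame = analysis_frame()
        frame = frame[frame["level"] == "yes"]
        with pytest.raises(StatsError, match="single level"):
            fit_group_model(frame, ModelSpec("log_EI", "tool_source"))

    def test_nonpositive_response_errors(self):
        frame = analysis_frame()
        frame.loc[frame.index[0], "EI_Nm2"] = 0.0
        with pytest.raises(StatsError, match="log"):
            fit_group_model(frame, ModelSpec("log_EI", "tool_source"))

    def test_empty_frame_errors(self):
        with pytest.raises(StatsError, match="empty"):
            fit_group_model(
                pd.DataFrame(columns=["sample_id", "plant_id", "level", "EI_Nm2", "E_Pa", "I_m4"]),
                ModelSpec("log_EI", "tool_source"),
            )


class TestInvariances:
    def test_unit_rescaling_leaves_F_and_t_unchanged(self):
        """Multiplying EI by a constant shifts only the intercept on the log scale."""
        frame = analysis_frame()
        spec = ModelSpec("log_EI", "tool_source")
        res1 = fit_group_model(frame, spec)
        frame2 = frame.copy()
        frame2.attrs = dict(frame.attrs)
        frame2["EI_Nm2"] = frame2["EI_Nm2"] * 1e3
        res2 = fit_group_model(frame2, spec)
        f1 = res1.f_table.set_index("term")
        f2 = res2.f_table.set_index("term")
        for term in f1.index:
            assert f2.loc[term, "F"] == pytest.approx(f1.loc[term, "F"], rel=1e-8)
        for pair in res1.contrasts:
            assert res2.contrasts[pair]["t"] == pytest.approx(res1.contrasts[pair]["t"], rel=1e-8)
        d = res2.fixed_effects["(intercept)"][0] - res1.fixed_effects["(intercept)"][0]
        assert d == pytest.approx(math.log(1e3), rel=1e-9)

    def test_label_permutation_invariance(self):
        """Reversing the level order changes no F statistic and no adjusted p."""
        frame = analysis_frame(scheme_name="preference")
        spec = ModelSpec("log_EI", "preference")
        res1 = fit_group_model(frame, spec)
        frame2 = frame.copy()
        frame2.attrs = {"level_order": list(reversed(frame.attrs["level_order"]))}
        res2 = fit_group_model(frame2, spec)
        f1 = res1.f_table.set_index("term")
        f2 = res2.f_table.set_index("term")
        for term in f1.index:
            assert f2.loc[term, "F"] == pytest.approx(f1.loc[term, "F"], rel=1e-8)
        for (a, b), c in res1.contrasts.items():
            mirror = res2.contrasts.get((b, a)) or res2.contrasts.get((a, b))
            assert mirror["p_adjusted"] == pytest.approx(c["p_adjusted"], rel=1e-6, abs=1e-12)

    def test_contrast_antisymmetry(self):
        """contrast(a,b) = -contrast(b,a): EMM differences flip sign exactly."""
        frame = analysis_frame(scheme_name="preference")
        res = fit_group_model(frame, ModelSpec("log_EI", "preference"))
        for (a, b), c in res.contrasts.items():
            direct = res.emms[a][0] - res.emms[b][0]
            assert c["estimate"] == pytest.approx(direct, rel=1e-12)
            assert -(res.emms[b][0] - res.emms[a][0]) == c["estimate"]


class TestAnova:
    def test_matches_ols_when_no_plant_structure(self):
        """With one sample per plant the LMM collapses to OLS; the type-II F
        must match statsmodels OLS ANOVA."""
        import statsmodels.formula.api as smf

        # one sample per plant: the variance split is unidentifiable, the fit
        # collapses to the OLS boundary and is flagged singular
        frame = analysis_frame(samples_per_plant=1, plant_sd=0.0)
        spec = ModelSpec("log_E", "tool_source")
        with pytest.warns(UserWarning, match="singular"):
            res = fit_group_model(frame, spec)
        df = frame.assign(y=np.log(frame["E_Pa"]))
        ols = smf.ols("y ~ C(level)", df).fit()
        from statsmodels.stats.anova import anova_lm

        tab = anova_lm(ols, typ=2)
        f_ours = res.f_table.set_index("term").loc["tool_source", "F"]
        assert f_ours == pytest.approx(tab.loc["C(level)", "F"], rel=1e-8)

    def test_df_num_is_levels_minus_one(self):
        frame = analysis_frame(scheme_name="material_type")
        res = fit_group_model(frame, ModelSpec("log_EI", "material_type"))
        k = frame["level"].nunique()
        row = res.f_table.set_index("term").loc["material_type"]
        assert row["df_num"] == k - 1
        assert row["df_den"] > 0

    def test_unfitted_raises(self):
        frame = analysis_frame()
        res = fit_group_model(frame, ModelSpec("log_EI", "tool_source"))
        res.model.fitted = False
        with pytest.raises(StatsError):
            anova_type2(res)


class TestContrasts:
    def test_two_level_tukey_equals_unadjusted(self):
        frame = analysis_frame()
        res = fit_group_model(frame, ModelSpec("log_EI", "tool_source"))
        ((_, c),) = res.contrasts.items()
        assert c["p_adjusted"] == pytest.approx(c["p_unadjusted"], rel=1e-9)

    def test_adjusted_at_least_unadjusted(self):
        frame = analysis_frame(scheme_name="material_type")
        res = fit_group_model(frame, ModelSpec("log_E", "material_type"))
        assert len(res.contrasts) == math.comb(frame["level"].nunique(), 2)
        for c in res.contrasts.values():
            assert c["p_adjusted"] >= c["p_unadjusted"] - 1e-12

    def test_tukey_matches_scipy_reference(self):
        """Adjusted p recomputed directly from the studentized range."""
        from scipy.stats import studentized_range

        frame = analysis_frame(scheme_name="preference")
        res = fit_group_model(frame, ModelSpec("log_E", "preference"))
        k = len(res.levels)
        for c in res.contrasts.values():
            expect = studentized_range.sf(abs(c["t"]) * math.sqrt(2), k, c["df"])
            assert c["p_adjusted"] == pytest.approx(
                min(max(expect, c["p_unadjusted"]), 1.0), rel=1e-9
            )


class TestPercentDifference:
    def test_identical_groups_zero(self):
        frame = pd.DataFrame(
            {
                "level": ["a"] * 3 + ["b"] * 3,
                "EI_Nm2": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            }
        )
        assert percent_rigidity_difference(frame, "a", "b") == pytest.approx(0.0)

    def test_emm_difference_ln_2_75_gives_175(self):
        frame = analysis_frame()
        res = fit_group_model(frame, ModelSpec("log_EI", "tool_source"))
        res.emms = {"a": (1.0, 0.1), "b": (1.0 + math.log(2.75), 0.1)}
        assert percent_rigidity_difference(res, "a", "b", basis="emm") == pytest.approx(175.0)

    def test_median_ratio_0_49_gives_minus_51(self):
        frame = pd.DataFrame(
            {"level": ["a", "a", "b", "b"], "EI_Nm2": [1.0, 1.0, 0.49, 0.49]}
        )
        assert percent_rigidity_difference(frame, "a", "b") == pytest.approx(-51.0)

    def test_missing_level_errors(self):
        frame = pd.DataFrame({"level": ["a"], "EI_Nm2": [1.0]})
        with pytest.raises(StatsError, match="not present"):
            percent_rigidity_difference(frame, "a", "zz")

    def test_zero_median_errors(self):
        frame = pd.DataFrame({"level": ["a", "b"], "EI_Nm2": [0.0, 1.0]})
        with pytest.raises(StatsError, match="zero median"):
            percent_rigidity_difference(frame, "a", "b")


class TestParameterRecovery:
    def test_known_offset_recovered(self):
        """A 0.7 log-EI offset between preference levels is recovered within
        its 95% CI for most replicates (full calibration is in acceptance)."""
        from scipy.stats import t as student_t

        hits = 0
        reps = 20
        for seed in range(reps):
            cfg = SyntheticConfig(
                seed=seed,
                n_species={"most_preferred": 4, "less_preferred": 0, "never_used": 4},
                plants_per_species=8,
                species_sd=0.0,
                effect_logEI={"most_preferred": 0.0, "less_preferred": 0.0, "never_used": 0.7},
            )
            records, truth = generate_cohort(cfg)
            for r in records:
                t = truth[r.sample_id]
                r.EI, r.E, r.qc_pass = t.EI_true, t.E_true, True
            scheme = assign_scheme(records, "tool_source")
            frame = build_analysis_frame(records, scheme)
            res = fit_group_model(frame, ModelSpec("log_E", "tool_source"))
            # canonical coding: reference level "no" (never-used), so the
            # "yes" coefficient estimates -0.7
            est, se = res.fixed_effects["level[yes]"]
            ell = np.zeros(len(res.model.exog_names))
            ell[res.model.exog_names.index("level[yes]")] = 1.0
            crit = student_t.ppf(0.975, res.model.contrast_df(ell))
            if est - crit * se <= -0.7 <= est + crit * se:
                hits += 1
        assert hits >= reps - 3
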