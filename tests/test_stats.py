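"""Group × load inference, multiplicity, partial Spearman, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from reconfig_swm.errors import DataError, JoinError, SchemaError
from reconfig_swm.stats import (StatsConfig, association_battery, bonferroni_gate,
                                bootstrap_se, build_model_table,
                                fit_group_load_model, partial_spearman,
                                tukey_posthoc)


def make_table(n_subjects=40, seed=0, group_shift=0.0, subject_sd=0.0):
    rng = np.random.default_rng(seed)
    n = n_subjects
    groups = np.repeat(["young"] * (n - n // 2) + ["old"] * (n // 2), 3)
    subj_eff = np.repeat(rng.normal(0, subject_sd, n), 3)
    tab = pd.DataFrame({
        "subject": np.repeat([f"s{i}" for i in range(n)], 3),
        "age_group": groups,
        "load": ["dot1", "dot3", "dot5"] * n,
        "sex": np.repeat(rng.choice(["M", "F"], n), 3),
        "scanner": np.repeat(rng.choice(["pre", "post"], n), 3),
        "task_motion": np.repeat(rng.normal(0.06, 0.02, n), 3),
        "rest_motion": np.repeat(rng.normal(0.06, 0.02, n), 3),
    })
    tab["Y"] = (rng.normal(0, 1, 3 * n) + subj_eff
                + group_shift * (tab["age_group"] == "young"))
    return tab


class TestGroupLoadModel:
    def test_denominator_df_equals_nobs_minus_coefficients(self):
        tab = make_table(n_subjects=143)
        tab["rest_motion"] = 0.0  # task-only outcome: 9 informative coefficients
        out = fit_group_load_model(tab, "fixed_ols")
        # 143 × 3 = 429 rows, 9 fixed coefficients → 420
        assert (out["df2"] == 420).all()
        inter = out[out["term"] == "age_group:load"].iloc[0]
        assert inter["df1"] == 2

    def test_f_matches_extra_sum_of_squares_oracle(self):
        import statsmodels.formula.api as smf

        tab = make_table(n_subjects=30, seed=3)
        out = fit_group_load_model(tab, "fixed_ols").set_index("term")
        full = smf.ols("Y ~ age_group * load + sex + task_motion + rest_motion"
                       " + scanner", data=tab).fit()
        for term, reduced_formula in [
            ("age_group:load", "Y ~ age_group + load + sex + task_motion"
             " + rest_motion + scanner"),
            ("task_motion", "Y ~ age_group * load + sex + rest_motion + scanner"),
        ]:
            red = smf.ols(reduced_formula, data=tab).fit()
            q = full.df_model - red.df_model
            f_oracle = ((red.ssr - full.ssr) / q) / (full.ssr / full.df_resid)
            assert out.loc[term, "F"] == pytest.approx(f_oracle, rel=1e-10)

    def test_interaction_type1_calibration(self):
        # null Monte-Carlo at reduced replicates: exchangeable rows, so the
        # fixed-effects F for the interaction is exact
        hits = 0
        B = 200
        for b in range(B):
            tab = make_table(n_subjects=20, seed=1000 + b)
            out = fit_group_load_model(tab, "fixed_ols")
            p = out.loc[out["term"] == "age_group:load", "p"].iloc[0]
            hits += p < 0.05
        assert 0.02 <= hits / B <= 0.09

    def test_planted_group_effect_detected(self):
        tab = make_table(n_subjects=80, seed=5, group_shift=1.0)
        out = fit_group_load_model(tab, "fixed_ols").set_index("term")
        assert out.loc["age_group", "p"] < 0.001

    def test_lmm_mode_between_and_within_dfs(self):
        tab = make_table(n_subjects=30, seed=7, subject_sd=1.0)
        out = fit_group_load_model(tab, "lmm_satterthwaite").set_index("term")
        # between-subject covariate df ≈ subjects − between-coefficients;
        # within-subject terms get the within-stratum df (n_subj × 2)
        assert out.loc["task_motion", "df2"] == pytest.approx(24, abs=1.0)
        assert out.loc["age_group:load", "df2"] == pytest.approx(56, abs=1.5)
        assert out.loc["load", "df2"] == pytest.approx(56, abs=1.5)

    def test_unknown_mode_rejected(self):
        with pytest.raises(SchemaError):
            fit_group_load_model(make_table(10), "reml_kenward")

    def test_missing_column_rejected(self):
        with pytest.raises(SchemaError):
            fit_group_load_model(make_table(10).drop(columns=["sex"]), "fixed_ols")


class TestTukey:
    def test_fifteen_contrasts_for_2x3_grid(self):
        out = tukey_posthoc(make_table(30, seed=2))
        assert len(out) == 15  # C(6,2)

    def test_adjusted_p_at_least_unadjusted(self):
        out = tukey_posthoc(make_table(30, seed=4))
        assert (out["p_tukey"] >= out["p_unadjusted"] - 1e-12).all()

    def test_null_family_wise_control(self):
        # over null tables the family-wise rate of any adjusted p < 0.05
        # stays controlled, and typical minima are large
        mins = [tukey_posthoc(make_table(40, seed=200 + s))["p_tukey"].min()
                for s in range(20)]
        assert np.mean(np.asarray(mins) < 0.05) <= 0.15
        assert np.median(mins) > 0.2

    def test_planted_cell_difference_flagged(self):
        tab = make_table(80, seed=9)
        tab.loc[(tab["age_group"] == "old") & (tab["load"] == "dot5"), "Y"] += 3.0
        out = tukey_posthoc(tab)
        hit = out[(out["cell_a"] == "old|dot5") | (out["cell_b"] == "old|dot5")]
        assert (hit["p_tukey"] < 0.001).all()


class TestBonferroniGate:
    def test_threshold_is_family_alpha_over_networks(self):
        cfg = StatsConfig()
        assert cfg.per_network_alpha == pytest.approx(0.05 / 9)
        flags = bonferroni_gate([0.0055] + [1.0] * 8, cfg)
        assert flags[0] and not flags[1:].any()

    def test_p_just_above_gate_not_significant(self):
        flags = bonferroni_gate([0.0060] + [1.0] * 8)
        assert not flags.any()

    def test_wrong_count_rejected(self):
        with pytest.raises(SchemaError):
            bonferroni_gate([0.01] * 8)


class TestPartialSpearman:
    def test_identity(self, rng):
        x = rng.standard_normal(30)
        assert partial_spearman(x, x).rho == pytest.approx(1.0)

    def test_covariate_absorbs_x(self, rng):
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        res = partial_spearman(x, y, x[:, None])
        assert abs(res.rho) < 0.1

    def test_fixed_eight_row_oracle(self):
        x = np.array([1, 4, 2, 8, 5, 7, 3, 6], float)
        y = np.array([2, 3, 1, 7, 6, 8, 4, 5], float)
        c = np.array([1, 1, 2, 2, 3, 3, 4, 4], float)
        res = partial_spearman(x, y, c[:, None])
        # brute-force rank-residual oracle: rank, solve both small
        # regressions explicitly, correlate the residuals
        rx, ry, rc = sps.rankdata(x), sps.rankdata(y), sps.rankdata(c)
        X = np.column_stack([np.ones(8), rc])
        bx = np.linalg.solve(X.T @ X, X.T @ rx)
        by = np.linalg.solve(X.T @ X, X.T @ ry)
        ex, ey = rx - X @ bx, ry - X @ by
        rho_oracle = (ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey))
        assert res.rho == pytest.approx(rho_oracle, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        c = np.column_stack([rng.standard_normal(40), x + rng.standard_normal(40)])
        df = pd.DataFrame({"x": x, "y": y, "c1": c[:, 0], "c2": c[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                                    method="spearman")
        res = partial_spearman(x, y, c)
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_no_covariates_equals_plain_spearman(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        res = partial_spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        c = rng.standard_normal((20, 1))
        base = partial_spearman(x, y, c).rho
        warped = partial_spearman(np.exp(x), y**3, np.arctan(c)).rho
        assert warped == pytest.approx(base, abs=1e-12)

    def test_constant_variable_rejected(self):
        with pytest.raises(DataError):
            partial_spearman(np.ones(10), np.arange(10))

    def test_too_small_sample_rejected(self, rng):
        with pytest.raises(DataError):
            partial_spearman(rng.standard_normal(5), rng.standard_normal(5),
                             rng.standard_normal((5, 2)))


class TestBootstrap:
    def test_degenerate_perfect_correlation_zero_se(self):
        x = np.arange(20.0)
        res = bootstrap_se(x, x, None, StatsConfig(seed=1), n_iterations=100)
        assert res.bootstrap_se == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproducible(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        a = bootstrap_se(x, y, None, StatsConfig(seed=7), n_iterations=200)
        b = bootstrap_se(x, y, None, StatsConfig(seed=7), n_iterations=200)
        assert a.bootstrap_se == b.bootstrap_se

    def test_se_scale_is_sane(self, rng):
        # for plain Spearman at n, SE ≈ 1/sqrt(n − 3) under independence
        n = 100
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        res = bootstrap_se(x, y, None, StatsConfig(seed=3), n_iterations=500)
        assert res.bootstrap_se == pytest.approx(1 / np.sqrt(n - 3), rel=0.35)


class TestAssociationBattery:
    @staticmethod
    def _inputs(n=30, seed=0):
        rng = np.random.default_rng(seed)
        subs = [f"s{i}" for i in range(n)]
        sims = []
        for pair, comp in [("dot1-rest", "rest_task"), ("dot3-rest", "rest_task"),
                           ("dot3-dot1", "stepwise")]:
            for s in subs:
                sims.append({"subject": s, "comparison": comp, "pair": pair,
                             "scope": "global", "z": rng.normal(), "r": 0.5,
                             "n_edges": 100, "reason": ""})
        sims = pd.DataFrame(sims)
        behavior = pd.DataFrame([
            {"subject": s, "load": load, "n_trials": 20,
             "accuracy": rng.uniform(0.5, 1), "mean_rt_correct": rng.uniform(0.5, 1.5)}
            for s in subs for load in (1, 3, 5)])
        meta = pd.DataFrame([{
            "subject": s, "age_group": "young", "age": rng.normal(25, 4),
            "sex": rng.choice(["M", "F"]), "scanner": "pre",
            "task_motion": rng.uniform(0.03, 0.09),
            "rest_motion": rng.uniform(0.03, 0.09)} for s in subs])
        return sims, behavior, meta

    def test_stepwise_pair_uses_higher_load_behavior(self):
        sims, behavior, meta = self._inputs()
        # make dot3 accuracy a deterministic copy of the dot3-dot1 similarity
        key = sims[(sims["pair"] == "dot3-dot1")].set_index("subject")["z"]
        behavior.loc[behavior["load"] == 3, "accuracy"] = (
            behavior.loc[behavior["load"] == 3, "subject"].map(key).to_numpy())
        out = association_battery(sims, behavior, meta)
        row = out[(out["pair"] == "dot3-dot1") & (out["outcome"] == "accuracy")]
        assert row["rho"].iloc[0] > 0.9

    def test_rest_pairs_include_rest_motion_covariate(self):
        sims, behavior, meta = self._inputs()
        out = association_battery(sims, behavior, meta)
        rest_row = out[out["pair"] == "dot1-rest"].iloc[0]
        step_row = out[out["pair"] == "dot3-dot1"].iloc[0]
        assert "rest_motion" in rest_row["covariates"]
        assert "rest_motion" not in step_row["covariates"]

    def test_global_scope_judged_at_uncorrected_alpha(self):
        sims, behavior, meta = self._inputs()
        out = association_battery(sims, behavior, meta)
        assert (out["gate"] == "uncorrected").all()

    def test_subject_mismatch_raises_join_error(self):
        sims, behavior, meta = self._inputs()
        with pytest.raises(JoinError):
            association_battery(sims, behavior, meta[:-5])


class TestModelTableConstruction:
    def test_stepwise_task_pairs_have_zero_rest_motion(self, tiny_results):
        tab = build_model_table(tiny_results["similarities"],
                                tiny_results["metadata"], "stepwise")
        task_task = tab["load"].isin(["dot3-dot1", "dot5-dot3"])
        assert (tab.loc[task_task, "rest_motion"] == 0.0).all()
        assert (tab.loc[~task_task, "rest_motion"] > 0).all()
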