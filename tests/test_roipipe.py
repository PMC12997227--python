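"""ROI extraction, the random-intercept factorial model, ΔFMΘ battery."""
import numpy as np
import pandas as pd
import pytest

from fmtheta.roipipe import (
    delta_fmtheta,
    extract_roi,
    fit_power_lme,
    run_group_battery,
)
from fmtheta.spectral import TFRMap, WindowSpec


def small_tfr(power, mode="raw"):
    power = np.asarray(power, dtype=float)
    freqs = np.arange(3.0, 3.0 + 0.5 * power.shape[1], 0.5)
    times = 0.25 + 0.05 * np.arange(power.shape[2])
    return TFRMap(power, freqs, times, mode=mode)


class TestExtractROI:
    def test_single_voxel_roi_is_window_average(self):
        p = np.arange(24.0).reshape(2, 3, 4)
        tfr = small_tfr(p)
        w = WindowSpec(3.0, 3.5, 0.25, 0.30)
        expected = p[1, :2, :2].mean()
        assert extract_roi(tfr, [1], w) == pytest.approx(expected)

    def test_constant_map_any_roi(self):
        tfr = small_tfr(np.full((5, 2, 2), 3.3))
        assert extract_roi(tfr, np.arange(5), WindowSpec(3, 4, 0.25, 0.3)) == pytest.approx(3.3)

    def test_hand_built_two_voxel_mean(self):
        p = np.zeros((2, 1, 2))
        p[0, 0] = [1.0, 3.0]
        p[1, 0] = [5.0, 7.0]
        tfr = small_tfr(p)
        w = WindowSpec(3.0, 3.0, 0.25, 0.30)
        assert extract_roi(tfr, [0, 1], w) == pytest.approx(4.0)

    def test_empty_or_invalid_roi_rejected(self):
        tfr = small_tfr(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            extract_roi(tfr, [], WindowSpec(3, 4, 0.25, 0.3))
        with pytest.raises(ValueError):
            extract_roi(tfr, [5], WindowSpec(3, 4, 0.25, 0.3))


class TestDeltaFMTheta:
    def rel(self, power):
        return small_tfr(power, mode="relchange")

    def test_identical_conditions_give_zero(self):
        a = self.rel(np.random.default_rng(0).normal(size=(3, 2, 2)))
        assert delta_fmtheta(a, a, [0, 1, 2], WindowSpec(3, 4, 0.25, 0.3)) == 0.0

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(1)
        go = self.rel(rng.normal(size=(3, 2, 2)))
        nogo = self.rel(rng.normal(size=(3, 2, 2)))
        w = WindowSpec(3, 4, 0.25, 0.3)
        assert delta_fmtheta(go, nogo, [0, 2], w) == pytest.approx(
            -delta_fmtheta(nogo, go, [0, 2], w)
        )

    def test_requires_relchange_mode(self):
        raw = small_tfr(np.ones((2, 2, 2)), mode="raw")
        with pytest.raises(ValueError):
            delta_fmtheta(raw, raw, [0], WindowSpec(3, 4, 0.25, 0.3))


def simulate_power_table(
    n_per_group=8,
    group_eff=0.0,
    state_eff=0.0,
    cond_eff=0.0,
    subj_sd=1.0,
    noise_sd=1.0,
    seed=0,
):
    """Balanced 2x2x2 dataset with a random subject intercept."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for group in ("control", "stroke"):
        for _ in range(n_per_group):
            k += 1
            intercept = rng.normal(0.0, subj_sd)
            for state in ("baseline", "active"):
                for condition in ("Go", "NoGo"):
                    g = 1.0 if group == "control" else -1.0
                    s = 1.0 if state == "active" else -1.0
                    c = 1.0 if condition == "NoGo" else -1.0
                    y = (
                        intercept
                        + group_eff * g
                        + state_eff * s
                        + cond_eff * c
                        + rng.normal(0.0, noise_sd)
                    )
                    rows.append(
                        dict(subject=f"s{k:02d}", group=group, state=state,
                             condition=condition, power=y)
                    )
    return pd.DataFrame(rows)


def anova_oracle_f(table):
    """Expected-mean-squares oracle for the fully balanced equal-group design.

    Variance components from the classical ANOVA strata; Wald F from the
    orthogonal sum-to-zero design under the compound-symmetry covariance.
    """
    g = np.where(table["group"] == "control", 1.0, -1.0)
    s = np.where(table["state"] == "active", 1.0, -1.0)
    c = np.where(table["condition"] == "NoGo", 1.0, -1.0)
    X = np.column_stack([np.ones(len(table)), g, s, c, g * s, g * c, s * c, g * s * c])
    y = table["power"].to_numpy(float)
    subjects, idx = np.unique(table["subject"], return_inverse=True)
    n_subj, N, m = len(subjects), len(table), 4

    dummies = np.zeros((N, n_subj))
    dummies[np.arange(N), idx] = 1.0
    Z = np.column_stack([dummies, X[:, 2:]])  # subjects + within effects
    resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sigma_e2 = resid @ resid / (N - n_subj - 6)

    means = np.array([y[idx == i].mean() for i in range(n_subj)])
    g_subj = np.array([g[idx == i][0] for i in range(n_subj)])
    Xb = np.column_stack([np.ones(n_subj), g_subj])
    rb = means - Xb @ np.linalg.lstsq(Xb, means, rcond=None)[0]
    s_b2 = rb @ rb / (n_subj - 2)
    sigma_s2 = max(s_b2 - sigma_e2 / m, 0.0)

    beta = X.T @ y / N  # orthogonal +-1 design with equal group sizes
    out = {}
    names = ["Intercept", "Group", "State", "Condition", "Group:State",
             "Group:Condition", "State:Condition", "Group:State:Condition"]
    for j, name in enumerate(names[1:], start=1):
        between = name == "Group"
        var = (sigma_e2 + m * sigma_s2) / N if between else sigma_e2 / N
        out[name] = beta[j] ** 2 / var
    return out


class TestFitPowerLME:
    def test_matches_expected_mean_squares_oracle_on_balanced_data(self):
        table = simulate_power_table(
            group_eff=0.4, state_eff=0.6, cond_eff=0.3, subj_sd=0.8, seed=3
        )
        res = fit_power_lme(table)
        oracle = anova_oracle_f(table)
        for row in res.anova.itertuples():
            assert row.F == pytest.approx(oracle[row.term], rel=1e-6)
        assert res.anova["df2"].unique().tolist() == [len(table) - 8]

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        table = simulate_power_table(group_eff=0.5, state_eff=0.4, subj_sd=0.7, seed=4)
        res = fit_power_lme(table)
        g = np.where(table["group"] == "control", 1.0, -1.0)
        s = np.where(table["state"] == "active", 1.0, -1.0)
        c = np.where(table["condition"] == "NoGo", 1.0, -1.0)
        X = np.column_stack([np.ones(len(table)), g, s, c, g * s, g * c, s * c, g * s * c])
        md = sm.MixedLM(table["power"].to_numpy(), X, groups=table["subject"])
        fit = md.fit(reml=True)
        np.testing.assert_allclose(res.coef.to_numpy(), fit.params[:8], rtol=1e-4)
        assert res.var_residual == pytest.approx(float(fit.scale), rel=1e-3)
        assert res.var_subject == pytest.approx(float(np.asarray(fit.cov_re)[0, 0]), rel=2e-2)

    def test_eta_sq_recomputable_from_f_and_df(self):
        res = fit_power_lme(simulate_power_table(state_eff=0.5, seed=5))
        for row in res.anova.itertuples():
            assert row.eta_p2 == pytest.approx(
                row.F * row.df1 / (row.F * row.df1 + row.df2), abs=1e-12
            )

    def test_df2_convention_at_target_cohort_size(self):
        # 17 + 10 subjects, 4 cells each -> 108 observations, df2 = 100
        rows = []
        for i in range(27):
            group = "control" if i < 17 else "stroke"
            for state in ("baseline", "active"):
                for condition in ("Go", "NoGo"):
                    rows.append(
                        dict(subject=f"s{i:02d}", group=group, state=state,
                             condition=condition,
                             power=np.random.default_rng(i).normal() + i * 0.01)
                    )
        res = fit_power_lme(pd.DataFrame(rows))
        assert set(res.anova["df2"]) == {100}

    def test_pure_state_effect_recovered(self):
        hits, inter_eta = 0, []
        for seed in range(20):
            table = simulate_power_table(
                state_eff=0.6, subj_sd=0.8, noise_sd=1.0, seed=seed
            )
            res = fit_power_lme(table)
            a = res.anova.set_index("term")
            if a.loc["State", "p"] < 0.05:
                hits += 1
            inter_eta.append(
                a.loc[["Group:State", "Group:Condition", "State:Condition",
                       "Group:State:Condition"], "eta_p2"].median()
            )
        assert hits >= 17  # planted effect found in > 90% of simulations
        assert np.median(inter_eta) < 0.03

    def test_type_one_error_calibrated_on_null_data(self):
        rejections = {t: 0 for t in
                      ("Group", "State", "Condition", "Group:State",
                       "Group:Condition", "State:Condition", "Group:State:Condition")}
        n_sim = 150
        for seed in range(n_sim):
            table = simulate_power_table(subj_sd=0.8, seed=1000 + seed)
            a = fit_power_lme(table).anova.set_index("term")
            for t in rejections:
                rejections[t] += int(a.loc[t, "p"] < 0.05)
        for t, k in rejections.items():
            # 99.9% binomial band around 0.05 at n_sim = 150
            assert 0 <= k / n_sim < 0.12, t

    def test_unbalanced_table_rejected(self):
        table = simulate_power_table(seed=6)
        with pytest.raises(ValueError):
            fit_power_lme(table.iloc[:-1])


class TestGroupBattery:
    def make_inputs(self, seed=0, shift=1.0):
        rng = np.random.default_rng(seed)
        table = simulate_power_table(n_per_group=6, state_eff=0.5, seed=seed)
        deltas = pd.DataFrame(
            {
                "subject": [f"d{i}" for i in range(12)],
                "group": ["control"] * 6 + ["stroke"] * 6,
                "delta_fmtheta": np.concatenate(
                    [rng.normal(shift, 1.0, 6), rng.normal(0.0, 1.0, 6)]
                ),
            }
        )
        return table, deltas

    def test_report_structure_and_determinism(self):
        table, deltas = self.make_inputs()
        a = run_group_battery(table, deltas, seed=2, n_boot=200)
        b = run_group_battery(table, deltas, seed=2, n_boot=200)
        assert a == b
        assert set(a["within_group"]) == {
            f"{g}:{c}:active_vs_baseline" for g in ("control", "stroke") for c in ("Go", "NoGo")
        }
        assert set(a["between_group"]) == {
            f"{s}:{c}:control_vs_stroke" for s in ("baseline", "active") for c in ("Go", "NoGo")
        }
        d = a["delta_fmtheta"]
        assert len(d["leave_one_out"]) == 6
        assert 0 <= d["bootstrap"]["p_stability"] <= 1

    def test_battery_serialisable_to_json(self):
        import json

        table, deltas = self.make_inputs(seed=1)
        report = run_group_battery(table, deltas, seed=0, n_boot=100)
        json.dumps(report)
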