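"""Accommodation models: LME fits, LRT, Nakagawa R², windows, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from vocalaccom.accommodation import (
    _fit_mixedlm,
    compare_prepost,
    fit_accommodation_lme,
    lrt_vs_null,
    nakagawa_r2,
    weekly_bootstrap_summary,
)


def simulate_records(
    rng,
    n_ind=4,
    n_weeks=16,
    n_calls=20,
    slope=-0.05,
    sex_slope_delta=0.0,
    ind_sd=0.3,
    noise_sd=0.4,
    intercept=1.0,
):
    """Direct ln-distance records: random intercepts + linear week effect."""
    rows = []
    weeks = [0.0, 0.5] + [float(w) for w in range(1, n_weeks + 1)]
    for i in range(n_ind):
        sex = "F" if i % 2 == 0 else "M"
        b_i = rng.normal(0, ind_sd)
        s = slope + (sex_slope_delta if sex == "M" else 0.0)
        for w in weeks:
            mu = intercept + b_i + s * w
            for _ in range(n_calls):
                rows.append(
                    {
                        "caller_id": f"I{i}",
                        "sex": sex,
                        "call_type": "trill",
                        "week": w,
                        "condition": "NewSoc" if w >= 1 else ("NewPhys" if w == 0.5 else "Before"),
                        "ln_distance": mu + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestFitAccommodationLME:
    def test_recovers_slope(self):
        rng = np.random.default_rng(0)
        rec = simulate_records(rng)
        m = fit_accommodation_lme(rec)
        b, se = m.terms.loc["week", "B"], m.terms.loc["week", "SE"]
        assert abs(b + 0.05) < 3 * se
        assert m.n_obs == len(rec)
        assert m.n_individuals == 4

    def test_drops_nonsignificant_interaction(self):
        rng = np.random.default_rng(1)
        m = fit_accommodation_lme(simulate_records(rng))
        assert not m.interaction_kept
        assert "sex_male:week" not in m.terms.index

    def test_keeps_real_interaction(self):
        rng = np.random.default_rng(2)
        rec = simulate_records(rng, sex_slope_delta=-0.04)
        m = fit_accommodation_lme(rec)
        assert m.interaction_kept
        assert m.terms.loc["sex_male:week", "B"] < 0

    def test_relabeling_individuals_changes_nothing(self):
        rng = np.random.default_rng(3)
        rec = simulate_records(rng)
        m1 = fit_accommodation_lme(rec)
        swapped = rec.copy()
        swapped["caller_id"] = swapped["caller_id"].map(
            {"I0": "Zz", "I1": "Aa", "I2": "Mm", "I3": "Bb"}
        )
        m2 = fit_accommodation_lme(swapped)
        assert m1.terms.loc["week", "B"] == pytest.approx(m2.terms.loc["week", "B"], abs=1e-8)
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-6)

    def test_constant_shift_moves_only_intercept(self):
        rng = np.random.default_rng(4)
        rec = simulate_records(rng)
        m1 = fit_accommodation_lme(rec)
        rec2 = rec.assign(ln_distance=rec["ln_distance"] + 3.0)
        m2 = fit_accommodation_lme(rec2)
        assert m2.terms.loc["Intercept", "B"] == pytest.approx(
            m1.terms.loc["Intercept", "B"] + 3.0, abs=1e-6
        )
        assert m2.terms.loc["week", "B"] == pytest.approx(m1.terms.loc["week", "B"], abs=1e-8)

    def test_input_validation(self):
        rng = np.random.default_rng(5)
        rec = simulate_records(rng, n_ind=1)
        with pytest.raises(ValueError, match="individuals"):
            fit_accommodation_lme(rec)


class TestLRT:
    def test_full_equals_null(self):
        rng = np.random.default_rng(6)
        rec = simulate_records(rng, slope=0.0)
        rec["sex_male"] = (rec["sex"] == "M").astype(float)
        res = _fit_mixedlm(rec, "ln_distance ~ week")
        chi2, df, p = lrt_vs_null(res, res)
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_nonnegative_and_df(self):
        rng = np.random.default_rng(7)
        rec = simulate_records(rng)
        m = fit_accommodation_lme(rec)
        assert m.lrt_chi2 >= 0
        assert m.lrt_df == len(m.terms) - 1
        assert 0 <= m.lrt_p <= 1

    def test_row_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        rec = simulate_records(rng)
        rec["sex_male"] = (rec["sex"] == "M").astype(float)
        full = _fit_mixedlm(rec, "ln_distance ~ week")
        null = _fit_mixedlm(rec.iloc[: len(rec) // 2], "ln_distance ~ 1")
        with pytest.raises(ValueError, match="different rows"):
            lrt_vs_null(full, null)


class TestNakagawaR2:
    def test_matches_manual_variance_decomposition(self):
        rng = np.random.default_rng(9)
        rec = simulate_records(rng, ind_sd=0.5)
        m = fit_accommodation_lme(rec)
        # oracle: rebuild the fixed predictor from the reported coefficients
        pred = np.full(len(rec), m.terms.loc["Intercept", "B"])
        pred += m.terms.loc["week", "B"] * rec["week"].to_numpy()
        pred += m.terms.loc["sex_male", "B"] * (rec["sex"] == "M").to_numpy(float)
        if "sex_male:week" in m.terms.index:
            pred += (
                m.terms.loc["sex_male:week", "B"]
                * (rec["sex"] == "M").to_numpy(float)
                * rec["week"].to_numpy()
            )
        var_f = np.var(pred, ddof=1)
        denom = var_f + m.re_variance + m.resid_variance
        assert m.r2_marginal == pytest.approx(var_f / denom, abs=1e-8)
        assert m.r2_conditional == pytest.approx((var_f + m.re_variance) / denom, abs=1e-8)
        assert m.r2_marginal <= m.r2_conditional <= 1.0

    def test_intercept_only_marginal_zero(self):
        rng = np.random.default_rng(10)
        rec = simulate_records(rng, slope=0.0, ind_sd=0.5)
        rec["sex_male"] = 0.0
        res = _fit_mixedlm(rec, "ln_distance ~ 1")
        r2m, r2c = nakagawa_r2(res)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert r2c > 0

    def test_zero_re_variance_makes_marginal_equal_conditional(self):
        rng = np.random.default_rng(11)
        rec = simulate_records(rng, ind_sd=0.0, n_ind=6)
        m = fit_accommodation_lme(rec)
        assert m.r2_marginal == pytest.approx(m.r2_conditional, abs=1e-4)


class TestComparePrePost:
    def test_convergence_negative_effect(self):
        rng = np.random.default_rng(12)
        rec = simulate_records(rng, slope=-0.05)
        r = compare_prepost(rec)
        assert r.condition_effect < 0
        assert r.condition_p < 0.05
        assert r.n_pre == 4 * 20

    def test_divergence_positive_effect(self):
        rng = np.random.default_rng(13)
        rec = simulate_records(rng, slope=0.009, noise_sd=0.3)
        r = compare_prepost(rec)
        assert r.condition_effect > 0

    def test_empty_window_errors(self):
        rng = np.random.default_rng(14)
        rec = simulate_records(rng)
        with pytest.raises(ValueError, match="empty window"):
            compare_prepost(rec[rec.condition != "NewPhys"])


class TestWeeklyBootstrap:
    def test_constant_values_zero_width_ci(self):
        rec = pd.DataFrame(
            {
                "caller_id": ["a"] * 8,
                "call_type": ["trill"] * 8,
                "week": [1.0] * 8,
                "ln_distance": [2.5] * 8,
            }
        )
        out = weekly_bootstrap_summary(rec, n_boot=200, seed=0)
        assert len(out) == 1
        assert out.loc[0, "ci_low"] == out.loc[0, "ci_high"] == 2.5

    def test_ci_contains_mean_and_small_cells_dropped(self):
        rng = np.random.default_rng(15)
        rec = simulate_records(rng, n_ind=2, n_weeks=3, n_calls=10)
        rec = pd.concat(
            [rec, rec.iloc[:3].assign(week=99.0)]  # a 3-call cell, below minimum
        )
        out = weekly_bootstrap_summary(rec, n_boot=500, seed=1)
        assert 99.0 not in out["week"].values
        assert ((out["ci_low"] <= out["mean_ln_distance"]) & (out["mean_ln_distance"] <= out["ci_high"])).all()

    def test_coverage_of_true_cell_mean(self):
        """Percentile-bootstrap CI covers the true cell mean ~95% of the time."""
        rng = np.random.default_rng(16)
        hits = 0
        n = 150
        for i in range(n):
            rec = pd.DataFrame(
                {
                    "caller_id": "a",
                    "call_type": "trill",
                    "week": 1.0,
                    "ln_distance": rng.normal(1.0, 0.5, 25),
                }
            )
            out = weekly_bootstrap_summary(rec, n_boot=400, seed=i)
            if out.loc[0, "ci_low"] <= 1.0 <= out.loc[0, "ci_high"]:
                hits += 1
        assert 0.88 <= hits / n <= 0.99
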