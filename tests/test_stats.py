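"""Regression models, BH-FDR, quintile contrasts and summary tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from delnet.stats import (CollinearityError, ModelSpec, bh_fdr, chi2_2x2,
                          extreme_quintile_test, fit_model, log_transform,
                          normality_screen, run_risk_factor_models,
                          summary_ttest)


# ---------------------------------------------------------------------------
# log transform


def test_log_transform_basics():
    df = pd.DataFrame({"a": [1.0, np.e, np.e**2], "b": [1, 2, 3]})
    out = log_transform(df, {})
    assert out.equals(df)  # empty list -> identity
    out = log_transform(df, {"a": 0.0})
    assert np.allclose(out["a"], [0.0, 1.0, 2.0])
    assert out["b"].equals(df["b"])
    with pytest.raises(ValueError):
        log_transform(pd.DataFrame({"a": [0.0, 1.0]}), {"a": 0.0})


def test_log_transform_normalizes_lognormal():
    """ln of a lognormal sample passes a Shapiro screen in >= 90% of reps."""
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.normal(0, 1, 200))
        out = log_transform(pd.DataFrame({"x": x}), {"x": 0.0})
        if sps.shapiro(out["x"]).pvalue > 0.05:
            hits += 1
    assert hits >= 45


# ---------------------------------------------------------------------------
# OLS with standardized betas


def test_outcome_on_itself_gives_unit_beta(rng):
    y = rng.standard_normal(50)
    df = pd.DataFrame({"y": y, "x": y})
    res = fit_model(df, ModelSpec("y", ("x",), adjusters=()))
    assert res.beta_std["x"] == pytest.approx(1.0)
    assert res.adj_r2 == pytest.approx(1.0)


def test_standardized_beta_affine_invariance(rng):
    n = 120
    x = rng.standard_normal(n)
    c = rng.standard_normal(n)
    y = 0.4 * x + 0.2 * c + rng.standard_normal(n)
    df = pd.DataFrame({"y": y, "x": x, "c": c})
    res = fit_model(df, ModelSpec("y", ("x",), adjusters=("c",)))
    df2 = pd.DataFrame({"y": 3.0 * y - 7.0, "x": 0.01 * x + 100.0, "c": c})
    res2 = fit_model(df2, ModelSpec("y", ("x",), adjusters=("c",)))
    assert res2.beta_std["x"] == pytest.approx(res.beta_std["x"], abs=1e-10)
    assert res2.p_values["x"] == pytest.approx(res.p_values["x"], abs=1e-10)


def test_age_dropped_from_adjusters_when_determinant(rng):
    n = 80
    df = pd.DataFrame({
        "y": rng.standard_normal(n), "age": rng.normal(70, 5, n),
        "center": rng.integers(0, 2, n), "gender": rng.integers(0, 2, n),
        "iq": rng.normal(100, 10, n),
    })
    spec = ModelSpec("y", ("age",))
    assert "age" not in spec.effective_adjusters()
    res = fit_model(df, spec)
    assert set(res.beta_std) == {"age", "center", "gender", "iq"}
    assert res.df_resid == n - 4 - 1


def test_collinear_design_names_aliased_column(rng):
    n = 40
    x = rng.standard_normal(n)
    df = pd.DataFrame({"y": rng.standard_normal(n), "x": x, "x2": 2 * x})
    with pytest.raises(CollinearityError) as exc:
        fit_model(df, ModelSpec("y", ("x", "x2"), adjusters=()))
    assert "x2" in exc.value.aliased


def test_null_model_pvalues_calibrated():
    """Pure-noise outcome: rejection rate at alpha=.05 in the binomial band."""
    rejections = 0
    n_sims = 1000
    for seed in range(n_sims):
        rng = np.random.default_rng(seed)
        n = 60
        df = pd.DataFrame({
            "y": rng.standard_normal(n), "x": rng.standard_normal(n),
            "center": rng.integers(0, 2, n), "gender": rng.integers(0, 2, n),
            "iq": rng.normal(100, 10, n),
        })
        res = fit_model(df, ModelSpec("y", ("x",),
                                      adjusters=("center", "gender", "iq")))
        rejections += res.p_values["x"] < 0.05
    rate = rejections / n_sims
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
    assert abs(rate - 0.05) <= half


# ---------------------------------------------------------------------------
# BH-FDR


def test_bh_fdr_step_up_hand_oracles():
    adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04)
    assert rej.all()
    adj, rej = bh_fdr([0.004, 0.03, 0.04, 0.8])
    assert np.allclose(adj, [0.016, 0.8 / 15, 0.8 / 15, 0.8], atol=1e-12)
    assert list(rej) == [True, False, False, False]
    adj, rej = bh_fdr([0.5])
    assert adj[0] == 0.5 and not rej[0]


def test_bh_fdr_matches_statsmodels(rng):
    for _ in range(200):
        m = int(rng.integers(1, 50))
        p = rng.random(m)
        adj, rej = bh_fdr(p)
        sm_rej, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, sm_adj, atol=1e-12)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=30))
def test_bh_fdr_monotone_in_sorted_order(p):
    adj, _ = bh_fdr(p)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)
    assert np.all((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0))


# ---------------------------------------------------------------------------
# extreme quintiles


def test_quintile_partition_1_to_10():
    v = np.arange(1.0, 11.0)
    y = v.copy()
    t, p, n_low, n_high = extreme_quintile_test(v, y)
    assert (n_low, n_high) == (2, 2)  # {1,2} vs {9,10}
    assert t > 0


def test_quintile_identical_outcomes_t_zero(rng):
    v = np.arange(20.0)
    y = np.ones(20)
    t, p, *_ = extreme_quintile_test(v, y)
    assert t == 0.0


def test_quintile_t_matches_textbook_oracle():
    """Two groups of 5 with known means/sds: Welch t computed by hand."""
    v = np.array([1.0] * 5 + [5.0] * 10 + [9.0] * 5)
    low_y = np.array([1.0, 2, 3, 4, 5])       # mean 3, var 2.5
    high_y = np.array([3.0, 4, 5, 6, 7])      # mean 5, var 2.5
    y = np.concatenate([low_y, np.zeros(10), high_y])
    t, p, n_low, n_high = extreme_quintile_test(v, y)
    assert (n_low, n_high) == (5, 5)
    assert t == pytest.approx((5 - 3) / np.sqrt(2.5 / 5 + 2.5 / 5))
    with pytest.raises(ValueError):
        # ties/small n collapse the lowest quintile to a single subject
        extreme_quintile_test(np.array([1.0, 2.0, 3.0, 4.0]), np.arange(4.0))


# ---------------------------------------------------------------------------
# summary t and chi-square


def test_summary_welch_t_reproduces_cohort_comparisons():
    """Printed (mean, SD, n) pairs give the published t values at 2 dp."""
    t_age, p_age = summary_ttest(72.1, 5.0, 554, 71.2, 4.9, 222)
    assert round(t_age, 2) == 2.30
    t_mmse, _ = summary_ttest(28.6, 1.4, 554, 28.7, 1.4, 222)
    assert round(t_mmse, 2) == -0.90
    t_iq, _ = summary_ttest(105, 12.7, 554, 105, 12.2, 222)
    assert round(t_iq, 2) == 0.00
    # Barthel reproduces at 2 dp only under the pooled-variance variant
    t_bi, _ = summary_ttest(98.2, 5.0, 554, 98.4, 4.8, 222, method="pooled")
    assert round(t_bi, 2) == -0.51
    assert summary_ttest(5.0, 0.0, 10, 5.0, 0.0, 10) == (0.0, 1.0)


def test_summary_t_equals_direct_welch_on_raw_data(rng):
    a = rng.normal(0, 1, 30)
    b = rng.normal(0.5, 2, 40)
    t_direct, p_direct = sps.ttest_ind(a, b, equal_var=False)
    t_sum, p_sum = summary_ttest(a.mean(), a.std(ddof=1), 30,
                                 b.mean(), b.std(ddof=1), 40)
    assert t_sum == pytest.approx(t_direct, abs=1e-12)
    assert p_sum == pytest.approx(p_direct, abs=1e-12)


def test_chi2_2x2_oracles():
    chi2, p = chi2_2x2([[10, 10], [10, 10]])
    assert chi2 == 0.0
    # hand oracle: all expected counts 15, chi2 = 4 * 25/15
    chi2, _ = chi2_2x2([[20, 10], [10, 20]])
    assert chi2 == pytest.approx(4 * 25 / 15)
    # alcohol-misuse style table: chi2 ~ 0, p = 0.9757 (prints as 0.975)
    _, p = chi2_2x2([[25, 485], [11, 211]])
    assert p == pytest.approx(0.9757, abs=1e-3)
    with pytest.raises(ValueError):
        chi2_2x2([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# model families


def test_run_risk_factor_models_fdr_family_per_determinant(rng):
    n = 100
    data = pd.DataFrame({
        "age": rng.normal(71, 5, n), "mmse": rng.normal(28, 1.5, n),
        "center": rng.integers(0, 2, n), "gender": rng.integers(0, 2, n),
        "iq": rng.normal(100, 10, n),
    })
    for o in ("strength", "diameter", "leaf_fraction"):
        data[o] = rng.standard_normal(n)
    table = run_risk_factor_models(data, ["age", "mmse"],
                                   outcomes=("strength", "diameter",
                                             "leaf_fraction"))
    assert len(table) == 6
    for det, grp in table.groupby("determinant"):
        adj, rej = bh_fdr(grp["p"].to_numpy())
        assert np.allclose(np.sort(adj), np.sort(grp["fdr_p"].to_numpy()))
    comb = run_risk_factor_models(data, ["age", "mmse"], combined=True,
                                  outcomes=("strength",))
    assert set(comb.determinant) == {"age", "mmse"}
    assert comb.model.eq("combined").all()


def test_normality_screen_flags_lognormal_only():
    rng = np.random.default_rng(12)
    df = pd.DataFrame({"skewed": np.exp(rng.normal(0, 1, 300)),
                       "gaussian": rng.normal(0, 1, 300)})
    flagged = normality_screen(df)
    assert "skewed" in flagged and "gaussian" not in flagged


def test_bh_family_null_false_discovery_controlled():
    """All-null 5-outcome families: any-rejection rate stays below q."""
    any_rej = 0
    n_sims = 300
    for seed in range(n_sims):
        rng = np.random.default_rng(seed)
        n = 120
        data = pd.DataFrame({
            "age": rng.normal(71, 5, n), "center": rng.integers(0, 2, n),
            "gender": rng.integers(0, 2, n), "iq": rng.normal(100, 10, n)})
        for o in ("strength", "diameter", "leaf_fraction",
                  "pcc_dlpfc_left", "pcc_dlpfc_right"):
            data[o] = rng.standard_normal(n)
        table = run_risk_factor_models(data, ["age"])
        any_rej += table.significant.any()
    rate = any_rej / n_sims
    assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
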