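"""Spearman screen, nested mixed models, VIF, ICC, post-hoc power."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ccpsv import (
    CohortSimParams,
    PowerInput,
    fit_mixed,
    generate_cohort,
    icc_repeatability,
    posthoc_power,
    spearman_screen,
    vif,
)

# ---- Spearman ----


def test_spearman_monotone_and_hand_computed_cases():
    df = pd.DataFrame(
        {
            "x": [1.0, 2.0, 3.0, 4.0, 5.0],
            "ident": [1.0, 2.0, 3.0, 4.0, 5.0],
            "cube": [-1.0, -8.0, -27.0, -64.0, -125.0],
            "perm": [2.0, 1.0, 4.0, 3.0, 5.0],
            "const": [1.0] * 5,
        }
    )
    res = {t.name: t for t in spearman_screen(df, "x", ["ident", "cube", "perm", "const"])}
    assert res["ident"].estimate == pytest.approx(1.0)
    assert res["cube"].estimate == pytest.approx(-1.0)
    # rank differences d=(−1,1,−1,1,0), Σd²=4 ⇒ ρ = 1 − 6·4/(5·24) = 0.8
    assert res["perm"].estimate == pytest.approx(0.8)
    assert np.isnan(res["const"].estimate)  # undefined, reported as missing


# ---- mixed model ----


def test_zero_variance_cohort_matches_ols():
    p = CohortSimParams(
        n_subjects=60,
        fixed_effects={"intercept": 10.0, "age_y": 0.3, "axl_mm": -1.0},
        sd_subject=0.0,
        sd_eye=0.0,
        sd_resid=2.0,
        seed=8,
    )
    df = generate_cohort(p)
    m = fit_mixed(df, "fd_psv", ["age_y", "axl_mm"])
    X = sm.add_constant(df[["age_y", "axl_mm"]])
    ols = sm.OLS(df["fd_psv"], X).fit()
    for name, ols_name in [("Intercept", "const"), ("age_y", "age_y"), ("axl_mm", "axl_mm")]:
        got = m.term(name).estimate
        want = ols.params[ols_name]
        assert abs(got - want) / max(abs(want), 1e-9) < 1e-4
    assert m.boundary_fit  # variance components on the zero boundary, flagged


def test_mixed_fit_recovers_generating_effects():
    p = CohortSimParams(n_subjects=300, seed=4)
    df = generate_cohort(p)
    m = fit_mixed(
        df,
        "fd_psv",
        ["age_y", "axl_mm", "se_d", "ct_um", "global_ccfd_pct", "area_mm2", "vfd_mm"],
    )
    assert m.term("global_ccfd_pct").estimate == pytest.approx(1.02, rel=0.1)
    assert m.term("axl_mm").estimate < 0
    assert m.n_subjects == 300
    assert 0.0 < m.r2 < 1.0
    assert m.var_subject > 0 and m.var_resid > 0


def test_mixed_fit_grouping_contracts():
    df = generate_cohort(CohortSimParams(n_subjects=5, seed=1))
    single = df[df.subject_id == df.subject_id.iloc[0]]
    with pytest.raises(ValueError, match="2 subjects"):
        fit_mixed(single, "fd_psv", ["age_y"])
    broken = df.copy()
    broken.loc[:, "eye_id"] = "shared_eye"  # one eye id across all subjects
    with pytest.raises(ValueError, match="nested"):
        fit_mixed(broken, "fd_psv", ["age_y"])


# ---- VIF ----


def test_vif_orthogonal_duplicated_and_closed_form():
    df = pd.DataFrame(
        {"a": [1.0, 1.0, -1.0, -1.0], "b": [1.0, -1.0, 1.0, -1.0]}
    )
    df["dup"] = df["a"]
    res = dict(vif(df, ["a", "b"]))
    assert res["a"] == pytest.approx(1.0, abs=1e-12)
    assert res["b"] == pytest.approx(1.0, abs=1e-12)
    res2 = dict(vif(df, ["a", "dup"]))
    assert np.isinf(res2["a"]) and np.isinf(res2["dup"])
    # two-predictor closed form 1/(1−r²) to 1e−10
    rng = np.random.default_rng(12)
    x = rng.normal(size=200)
    y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=200)
    df3 = pd.DataFrame({"x": x, "y": y})
    r = np.corrcoef(x, y)[0, 1]
    res3 = dict(vif(df3, ["x", "y"]))
    assert res3["x"] == pytest.approx(1.0 / (1.0 - r**2), abs=1e-10)
    assert res3["y"] == pytest.approx(1.0 / (1.0 - r**2), abs=1e-10)


def test_vif_needs_enough_rows():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    with pytest.raises(ValueError):
        vif(df, ["a", "b"])


# ---- ICC ----


def test_icc_is_one_for_identical_sessions():
    rng = np.random.default_rng(3)
    s1 = rng.normal(10, 5, size=20)
    icc, lo, hi = icc_repeatability(s1, s1.copy())
    assert icc == pytest.approx(1.0)


def test_icc_near_zero_for_independent_sessions():
    rng = np.random.default_rng(4)
    icc, _, _ = icc_repeatability(rng.normal(size=500), rng.normal(size=500))
    assert abs(icc) < 0.1


def test_icc_matches_variance_ratio_closed_form():
    # between-item SD 10, within-session SD 3 ⇒ ICC ≈ 100/109 ≈ 0.917
    rng = np.random.default_rng(5)
    truth = rng.normal(50, 10, size=2000)
    s1 = truth + rng.normal(0, 3, size=2000)
    s2 = truth + rng.normal(0, 3, size=2000)
    icc, lo, hi = icc_repeatability(s1, s2)
    assert icc == pytest.approx(100.0 / 109.0, abs=0.02)
    assert lo <= icc <= hi


def test_icc_degenerate_and_input_contracts():
    icc, lo, hi = icc_repeatability(np.full(10, 2.0), np.full(10, 2.0))
    assert np.isnan(icc)
    with pytest.raises(ValueError):
        icc_repeatability(np.arange(3.0), np.arange(3.0))


# ---- power ----


def test_power_equals_alpha_under_the_null():
    p = posthoc_power(PowerInput(beta_hat=0.0, se=1.0, n_eff=31, alpha=0.05))
    assert p == pytest.approx(0.05, abs=1e-10)


def test_power_approaches_one_for_huge_effects():
    assert posthoc_power(PowerInput(beta_hat=100.0, se=1.0, n_eff=31)) > 0.9999


def test_power_half_at_critical_noncentrality():
    # ncp = t_crit ⇒ power ≈ 0.5 by near-symmetry of the noncentral t
    p = posthoc_power(PowerInput(beta_hat=1.96, se=1.0, n_eff=5000))
    assert p == pytest.approx(0.5, abs=0.01)


def test_power_monotone_in_effect_and_sample_size():
    grid = [posthoc_power(PowerInput(beta_hat=b, se=1.0, n_eff=31)) for b in (0.5, 1.0, 2.0, 3.0)]
    assert all(a < b for a, b in zip(grid, grid[1:]))
    byn = [posthoc_power(PowerInput(beta_hat=1.0, se=1.0, n_eff=n)) for n in (5, 10, 40)]
    assert all(a < b for a, b in zip(byn, byn[1:]))
    with pytest.raises(ValueError):
        posthoc_power(PowerInput(beta_hat=1.0, se=1.0, n_eff=2))
    with pytest.raises(ValueError):
        PowerInput(beta_hat=1.0, se=0.0, n_eff=10)
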