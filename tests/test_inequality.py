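import numpy as np
import pandas as pd
import pytest

import envineq as ei
from envineq.errors import AlignmentError, InvalidArgumentError
from envineq.inequality import (
    kruskal_wallis_h,
    polluted_indicator,
    smooth_gradient,
)


# --------------------------------------------------------------------------
# Kruskal–Wallis


def test_worked_example_hand_ranksum():
    """H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1) = 27/7 for {1..6} in 3+3."""
    h, df, p = kruskal_wallis_h([1, 2, 3, 4, 5, 6], ["A", "A", "A", "B", "B", "B"])
    assert h == pytest.approx(27.0 / 7.0, abs=1e-3)
    assert df == 1
    assert 0.04 < p < 0.06


def test_shift_invariance():
    vals = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.0, 3.5])
    groups = np.array(list("AABBABAB"))
    h1, _, _ = kruskal_wallis_h(vals, groups)
    h2, _, _ = kruskal_wallis_h(vals + 100.0, groups)
    assert h1 == pytest.approx(h2, abs=1e-12)


def test_identical_values_convention():
    h, df, p = kruskal_wallis_h([5.0] * 8, ["A"] * 4 + ["B"] * 4)
    assert (h, p) == (0.0, 1.0)
    assert df == 1


def test_single_group_rejected():
    with pytest.raises(InvalidArgumentError):
        kruskal_wallis_h([1, 2, 3], ["A", "A", "A"])
    with pytest.raises(InvalidArgumentError):
        kruskal_wallis_h([], [])


# --------------------------------------------------------------------------
# penalized-spline smooth


def test_smooth_null_case_flat_line():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, 200)
    y = 3.0 + rng.normal(0, 1e-6, 200)
    fit = smooth_gradient(y, x)
    assert fit.p_value > 0.5
    assert fit.edf < 1.6


def test_smooth_recovers_linear_truth():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, 584)
    y = 2.0 * x + rng.normal(0, 0.1, 584)
    fit = smooth_gradient(y, x)
    assert fit.p_value < 0.01
    ref = 2.0 * fit.grid
    inner = (fit.grid > np.quantile(x, 0.02)) & (fit.grid < np.quantile(x, 0.98))
    assert np.max(np.abs(fit.fitted[inner] - ref[inner])) < 0.05
    assert fit.slope_sign > 0


def test_smooth_recovers_sine():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 2 * np.pi, 584)
    y = np.sin(x) + rng.normal(0, 0.05, 584)
    fit = smooth_gradient(y, x)
    rmse = np.sqrt(np.mean((fit.fitted - np.sin(fit.grid)) ** 2))
    assert rmse < 0.1


def test_smooth_agrees_with_statsmodels_gam():
    """Independent penalized-GAM route flags the same linear signal."""
    from statsmodels.gam.api import BSplines, GLMGam

    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, 400)
    y = 1.5 * x + rng.normal(0, 0.2, 400)
    ours = smooth_gradient(y, x)
    bs = BSplines(x[:, None], df=[10], degree=[3])
    gam = GLMGam(y, np.ones((400, 1)), smoother=bs, alpha=[1.0])
    gam.scale = None
    alpha = gam.select_penweight(criterion="gcv")[0]
    res = GLMGam(y, np.ones((400, 1)), smoother=bs, alpha=alpha).fit()
    theirs = res.test_significance(0)
    assert ours.p_value < 0.01
    assert float(np.squeeze(theirs.pvalue)) < 0.01


def test_smooth_degenerate_income_rejected():
    with pytest.raises(InvalidArgumentError):
        smooth_gradient(np.arange(30.0), np.full(30, 5.0))
    with pytest.raises(InvalidArgumentError):
        smooth_gradient(np.arange(10.0), np.arange(10.0))


# --------------------------------------------------------------------------
# polluted indicator


def frame(values_by_year):
    rows = []
    for year, vals in values_by_year.items():
        for i, v in enumerate(vals, start=1):
            rows.append({"area_id": i, "year": year, "h": float(v)})
    return pd.DataFrame(rows)


def test_single_hazard_top_two_quintiles():
    tab = frame({2007: [1, 2, 3, 4, 5]})
    out = polluted_indicator(tab, ["h"])
    np.testing.assert_array_equal(out["polluted"], [0, 0, 0, 1, 1])


def test_rule_semantics_all_vs_any():
    tab = frame({2007: [1, 2, 3, 4, 5]})
    tab["g"] = [5.0, 4.0, 3.0, 2.0, 1.0]  # anti-correlated hazard
    allr = polluted_indicator(tab, ["h", "g"], quintile_rule="all")
    anyr = polluted_indicator(tab, ["h", "g"], quintile_rule="any")
    assert allr["polluted"].sum() == 0
    np.testing.assert_array_equal(anyr["polluted"], [1, 1, 0, 1, 1])


def test_perfectly_correlated_hazards_flag_two_fifths():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=10)
    tab = frame({2007: vals, 2008: rng.normal(size=10)})
    tab["g"] = np.exp(tab["h"])  # monotone transform: same ranks
    out = polluted_indicator(tab, ["h", "g"], quintile_rule="all")
    for year, sub in out.groupby("year"):
        assert sub["polluted"].sum() == 4  # 2/5 of 10 areas


def test_indicator_monotone_invariance():
    rng = np.random.default_rng(5)
    tab = frame({2007: rng.normal(size=15)})
    a = polluted_indicator(tab, ["h"])
    tab2 = tab.copy()
    tab2["h"] = 10.0 * np.exp(tab2["h"])
    b = polluted_indicator(tab2, ["h"])
    np.testing.assert_array_equal(a["polluted"], b["polluted"])


def test_missing_hazard_rejected():
    tab = frame({2007: [1, 2, 3, 4, 5]})
    with pytest.raises(AlignmentError):
        polluted_indicator(tab, ["h", "missing"])
    with pytest.raises(InvalidArgumentError):
        polluted_indicator(tab, ["h"], quintile_rule="most")


# --------------------------------------------------------------------------
# susceptibility report plumbing


def test_susceptibility_report_structure_and_inestimable(geom_small):
    """All-zero indicator: lambda and interaction rows are flagged inestimable;
    rows come in reporting order (main effect, quintile mains, interactions)."""
    from conftest import make_panel
    from envineq.design import ModelSpec
    from envineq.inequality import fit_susceptibility
    from envineq.synthetic import SimulationTruth, simulate_deaths

    panel = make_panel(geom_small, years=3, pop=8_000)
    pairs = panel[["area_id", "year"]].drop_duplicates()
    ind = pairs.assign(polluted=0)
    truth = SimulationTruth(
        coefficients={"intercept": np.log(0.01)},
        spec_kwargs=dict(form="polluted", include_foreigners=False,
                         include_housing=False, include_age=False,
                         include_land_use=False),
        spatial_sd=0.0, alpha_sd=0.0, rw1_sd=0.0, eta_sd=0.0,
    )
    panel = simulate_deaths(panel, ind, truth, seed=11, geom=geom_small)
    spec = ModelSpec(sex="male", form="polluted", include_foreigners=False,
                     include_housing=False, include_age=False,
                     include_land_use=False).without_random_effects()
    report = fit_susceptibility(panel, ind, spec, geom=geom_small, seed=1)
    rows = report.rows
    assert list(rows["term"][:3]) == ["non_polluted", "polluted", "income_q1"]
    inter = rows[rows["term"].str.startswith("polluted:")]
    assert len(inter) == 4
    pol = rows.set_index("term")
    assert not pol.loc["polluted", "estimable"]
    assert pol.loc["polluted", "formatted"] == "inestimable"
    assert not pol.loc["polluted:q5", "estimable"]
    assert pol.loc["non_polluted", "RR"] == 1.0
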