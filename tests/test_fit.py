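import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import envineq as ei
from envineq.design import ModelSpec, build_design
from envineq.errors import PoolingError
from envineq.fit import (
    HealthFit,
    fit_health_model,
    format_rr,
    pool_over_draws,
    relative_risks,
)
from envineq.synthetic import SimulationTruth, exposure_table, simulate_deaths

from conftest import make_panel


@pytest.fixture(scope="module")
def small_setup(geom_small):
    panel0 = ei.generate_covariates(geom_small, 4, seed=31)
    income = panel0[panel0.sex == "male"][["area_id", "year", "income"]]
    field = ei.generate_exposure_fields(
        geom_small, 4,
        [ei.HazardConfig(name="pm", intercept=20.0, matern_sd=3.0, matern_range=0.3,
                         income_gradient=-1.5, temporal_ar=0.8, lattice_n=25)],
        seed=32, income=income,
    )[0]
    expo = exposure_table([field], geom_small)
    truth = SimulationTruth(
        coefficients={"intercept": np.log(0.01), "income_q5": -0.1, "pm": 0.05},
        spec_kwargs=dict(form="hazard", pollutant="pm", noise=(),
                         include_land_use=False, include_foreigners=False,
                         pollutant_quintile_interaction=False,
                         noise_quintile_interaction=False),
        spatial_sd=0.05, alpha_sd=0.05, rw1_sd=0.05, eta_sd=0.03,
    )
    panel = simulate_deaths(panel0, expo, truth, seed=33, geom=geom_small)
    return panel, expo, truth


def test_glm_limit_matches_statsmodels_irls(small_setup, geom_small):
    """Random effects off: Laplace fit equals an independent IRLS Poisson GLM."""
    panel, expo, truth = small_setup
    spec = truth.model_spec("male").without_random_effects()
    design = build_design(panel, expo, spec, geom=geom_small)
    fit = fit_health_model(design, spec)
    glm = sm.GLM(design.y, design.X, family=sm.families.Poisson(),
                 offset=design.offset).fit()
    assert np.abs(fit.mean - glm.params).max() < 1e-3


def test_offset_contract(small_setup, geom_small):
    """Doubling Pop_it (deaths fixed) shifts only the intercept, by -ln 2."""
    panel, expo, truth = small_setup
    spec = truth.model_spec("male").without_random_effects()
    d1 = build_design(panel, expo, spec, geom=geom_small)
    doubled = panel.copy()
    doubled["pop"] = doubled["pop"] * 2
    doubled["density"] = doubled["density"] * 2
    d2 = build_design(doubled, expo, spec, geom=geom_small)
    f1 = fit_health_model(d1, spec)
    f2 = fit_health_model(d2, spec)
    i = d1.columns.index("intercept")
    assert f2.mean[i] - f1.mean[i] == pytest.approx(-math.log(2), abs=1e-6)
    others = np.delete(np.arange(d1.n_fixed), i)
    assert np.abs(f1.mean[others] - f2.mean[others]).max() < 1e-6


def test_null_model_intercept_is_log_crude_rate(geom_small):
    panel = make_panel(geom_small, years=3, pop=8_000)
    pairs = panel[["area_id", "year"]].drop_duplicates()
    ind = pairs.assign(polluted=0)
    truth = SimulationTruth(
        coefficients={"intercept": np.log(0.012)},
        spec_kwargs=dict(form="polluted", include_foreigners=False,
                         include_housing=False, include_age=False,
                         include_land_use=False, polluted_quintile_interaction=False),
        spatial_sd=0.0, alpha_sd=0.0, rw1_sd=0.0, eta_sd=0.0,
    )
    panel = simulate_deaths(panel, ind, truth, seed=3, geom=geom_small)
    spec = truth.model_spec("male").without_random_effects()
    design = build_design(panel, ind, spec, geom=geom_small)
    fit = fit_health_model(design, spec)
    i = design.columns.index("intercept")
    crude = math.log(design.y.sum() / np.exp(design.offset).sum())
    assert abs(fit.mean[i] - crude) < 2 * fit.sd[i] + 0.01


def test_rw1_posterior_sums_to_zero(small_setup, geom_small):
    panel, expo, truth = small_setup
    spec = truth.model_spec("male")
    design = build_design(panel, expo, spec, geom=geom_small)
    fit = fit_health_model(design, spec)
    assert abs(fit.random_effects["rw1"]["mean"].sum()) < 0.02
    assert abs(fit.random_effects["spatial"]["mean"].sum()) < 0.05


def test_laplace_and_mcmc_agree(small_setup, geom_small):
    """Fixed-effect posterior means agree within 0.05 on the log scale."""
    panel, expo, truth = small_setup
    spec = truth.model_spec("male")
    design = build_design(panel, expo, spec, geom=geom_small)
    lap = fit_health_model(design, spec)
    mcmc_spec = replace(spec, method="mcmc", mcmc_iterations=2500, mcmc_burn=1000)
    mcmc = fit_health_model(design, mcmc_spec, seed=99)
    assert np.abs(lap.mean - mcmc.mean).max() < 0.05
    assert mcmc.diagnostics["rhat_max"] < 1.1
    assert mcmc.diagnostics["ess_min"] > 50


def test_mutual_standardization_age_adjustment(geom_small):
    """Crude-rate response with age regressors removes the bias that omitting
    them induces when age structure tracks income."""
    rng = np.random.default_rng(8)
    income = np.linspace(50, 200, geom_small.n_areas)
    base = make_panel(geom_small, years=3, pop=10_000, income=income)
    rank = pd.Series(income).rank().to_numpy() / geom_small.n_areas
    p65 = 0.12 + 0.12 * rank
    p65_map = dict(zip(geom_small.area_ids, p65))
    base["pop65_frac"] = base["area_id"].map(p65_map)
    pairs = base[["area_id", "year"]].drop_duplicates()
    ind = pairs.assign(polluted=0)
    truth = SimulationTruth(
        coefficients={"intercept": np.log(0.01), "income_q5": -0.10,
                      "pop65_frac": 0.25},
        spec_kwargs=dict(form="polluted", include_foreigners=False,
                         include_housing=False, include_land_use=False,
                         polluted_quintile_interaction=False),
        spatial_sd=0.0, alpha_sd=0.0, rw1_sd=0.0, eta_sd=0.0,
    )
    spec_adj = truth.model_spec("male").without_random_effects()
    spec_omit = replace(spec_adj, include_age=False)
    est_adj, est_omit, delta2 = [], [], []
    for rep in range(10):
        panel = simulate_deaths(base, ind, truth, seed=600 + rep, geom=geom_small)
        fa = fit_health_model(build_design(panel, ind, spec_adj, geom=geom_small), spec_adj)
        fo = fit_health_model(build_design(panel, ind, spec_omit, geom=geom_small), spec_omit)
        est_adj.append(fa.coefficient("income_q5"))
        est_omit.append(fo.coefficient("income_q5"))
        delta2.append(fa.coefficient("pop65_frac"))
    bias_adj = abs(np.mean(est_adj) - (-0.10))
    bias_omit = abs(np.mean(est_omit) - (-0.10))
    assert bias_omit > bias_adj
    assert np.mean(delta2) == pytest.approx(0.25, abs=0.05)


def degenerate_fit(columns, means, var=1e-24):
    p = len(columns)
    return HealthFit(
        columns=columns, mean=np.array(means, dtype=float),
        cov=np.eye(p) * var, draws=None, scalers={}, hyper={},
        random_effects={}, method="laplace", provenance="plug-in",
        converged=True, diagnostics={}, log_marginal=0.0,
        spec=ModelSpec(form="polluted", include_foreigners=False),
    )


def test_rr_degenerate_at_zero_is_one_unflagged():
    fit = degenerate_fit(["intercept", "polluted"], [0.0, 0.0])
    rr = relative_risks(fit).set_index("term")
    assert rr.loc["polluted", "RR"] == pytest.approx(1.0, abs=1e-9)
    assert not rr.loc["polluted", "flag95"] and not rr.loc["polluted", "flag90"]


def test_rr_tight_posterior_formats_to_table_style():
    fit = degenerate_fit(["intercept", "polluted"], [0.0, math.log(2.0)])
    rr = relative_risks(fit).set_index("term")
    assert rr.loc["polluted", "formatted"] == "2.000 (2.000–2.000)"


def test_rr_format_matches_reporting_convention():
    assert format_rr(0.794, 0.632, 1.002) == "0.794 (0.632–1.002)"


def test_rr_backtransforms_standardized_scale():
    fit = degenerate_fit(["intercept", "pm"], [0.0, 0.5])
    fit.scalers = {"pm": (10.0, 5.0)}
    rr = relative_risks(fit).set_index("term")
    assert rr.loc["pm", "RR"] == pytest.approx(math.exp(0.1), abs=1e-9)


def test_pooling_identical_fits_is_stable(small_setup, geom_small):
    panel, expo, truth = small_setup
    spec = truth.model_spec("male").without_random_effects()
    design = build_design(panel, expo, spec, geom=geom_small)
    fit = fit_health_model(design, spec)
    pooled = pool_over_draws([fit, fit, fit], seed=0)
    assert pooled.provenance == "M-draw pooled"
    np.testing.assert_allclose(pooled.mean, fit.mean, atol=1e-9)
    assert np.abs(pooled.fixed_quantile(0.5) - fit.fixed_quantile(0.5)).max() < \
        4 * fit.sd.max() / math.sqrt(1000)


def test_pooled_variance_dominates_within_fit_variance(small_setup, geom_small):
    panel, expo, truth = small_setup
    spec = truth.model_spec("male").without_random_effects()
    fits = []
    for shift in (0.0, 0.5, 1.0):
        t = expo.copy()
        t["pm"] = t["pm"] + shift * t["pm"].std()
        d = build_design(panel, t, spec, geom=geom_small)
        fits.append(fit_health_model(d, spec))
    pooled = pool_over_draws(fits, seed=1)
    within = np.mean([np.diag(f.cov) for f in fits], axis=0)
    assert np.all(np.diag(pooled.cov) >= within - 1e-6)


def test_pooling_rejects_mismatched_specs(small_setup, geom_small):
    panel, expo, truth = small_setup
    spec = truth.model_spec("male").without_random_effects()
    design = build_design(panel, expo, spec, geom=geom_small)
    fit = fit_health_model(design, spec)
    other = degenerate_fit(["intercept"], [0.0])
    with pytest.raises(PoolingError):
        pool_over_draws([fit, other])
    with pytest.raises(PoolingError):
        pool_over_draws([fit])
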