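import numpy as np
import pytest

import envineq as ei
from envineq.errors import InvalidArgumentError
from envineq.synthetic import HazardConfig, generate_exposure_fields, place_stations


@pytest.fixture(scope="module")
def income_small(geom_small):
    panel = ei.generate_covariates(geom_small, 4, seed=21)
    return panel[panel.sex == "male"][["area_id", "year", "income"]]


def test_noiseless_gradient_is_monotone_in_income(geom_small, income_small):
    """With matern_sd = 0 the area-mean exposure is a deterministic, strictly
    decreasing function of (standardized) income when the gradient is negative."""
    cfg = HazardConfig(name="h", intercept=10.0, matern_sd=0.0, income_gradient=-2.0,
                       lattice_n=40)
    field = generate_exposure_fields(geom_small, 4, [cfg], seed=0, income=income_small)[0]
    tab = field.area_means(geom_small)
    year = tab["year"].iloc[0]
    sub = tab[tab["year"] == year].merge(
        income_small[income_small["year"] == year], on=["area_id", "year"]
    )
    srt = sub.sort_values("income")["h"].to_numpy()
    assert np.all(np.diff(srt) < 0)


def test_marginal_variance_calibrated(geom_small):
    """Lattice variance matches matern_sd**2 within Monte Carlo tolerance."""
    sd = 1.5
    cfg = HazardConfig(name="h", intercept=0.0, matern_sd=sd, matern_range=0.2,
                       temporal_ar=0.0, lattice_n=20)
    variances = []
    for rep in range(40):
        f = generate_exposure_fields(geom_small, 2, [cfg], seed=rep)[0]
        variances.append(f.values[0].var())
    mc_sd = np.std(variances) / np.sqrt(len(variances))
    assert abs(np.mean(variances) - sd**2) < 3 * mc_sd + 0.05 * sd**2


def test_spatial_correlation_decays_with_distance(geom_small):
    """Binned empirical correlogram of the field decreases over lag bins."""
    cfg = HazardConfig(name="h", intercept=0.0, matern_sd=1.0, matern_range=0.3,
                       temporal_ar=0.0, lattice_n=15)
    draws = []
    for rep in range(150):
        f = generate_exposure_fields(geom_small, 2, [cfg], seed=5000 + rep)[0]
        draws.append(f.values[0])
    draws = np.array(draws)
    pts = f.lattice
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    c = np.corrcoef(draws.T)
    bins = [0.05, 0.15, 0.25, 0.35, 0.5, 0.8]
    means = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        mask = (d > lo) & (d <= hi)
        means.append(c[mask].mean())
    assert np.all(np.diff(means) < 0)


def test_temporal_autocorrelation_matches_ar(geom_small):
    """Lag-1 autocorrelation of yearly area means recovers temporal_ar = 0.9."""
    cfg = HazardConfig(name="h", intercept=0.0, matern_sd=1.0, matern_range=0.3,
                       temporal_ar=0.9, lattice_n=12)
    acs = []
    for rep in range(25):
        f = generate_exposure_fields(geom_small, 150, [cfg], seed=900 + rep)[0]
        series = f.values.mean(axis=1)
        x0, x1 = series[:-1], series[1:]
        acs.append(np.corrcoef(x0, x1)[0, 1])
    assert abs(np.mean(acs) - 0.9) < 0.1


def test_station_record_arithmetic(geom_small, income_small):
    cfg = HazardConfig(name="h", intercept=30.0, matern_sd=2.0)
    f = generate_exposure_fields(geom_small, 8, [cfg], seed=1)[0]
    st = place_stations(f, 13, obs_sd=2.0, seed=2)
    assert len(st.records) == 13 * 8
    locs = st.records.groupby("station_id")[["x", "y"]].nunique()
    assert (locs == 1).all().all()


def test_zero_observation_noise_reproduces_surface(geom_small):
    cfg = HazardConfig(name="h", intercept=30.0, matern_sd=2.0)
    f = generate_exposure_fields(geom_small, 3, [cfg], seed=1)[0]
    st = place_stations(f, 5, obs_sd=0.0, seed=3)
    for _, row in st.records.iterrows():
        yi = f.years.index(row["year"])
        j = np.argmin(np.linalg.norm(f.lattice - [row["x"], row["y"]], axis=1))
        assert row["value"] == pytest.approx(f.values[yi, j], abs=1e-12)


def test_observation_noise_sd_calibrated(geom_small):
    """Sample sd of (observation - truth) over 10^4 records matches obs_sd = 1."""
    cfg = HazardConfig(name="h", intercept=0.0, matern_sd=1.0, temporal_ar=0.0,
                       lattice_n=10)
    f = generate_exposure_fields(geom_small, 200, [cfg], seed=4)[0]
    st = place_stations(f, 50, obs_sd=1.0, seed=5)
    resid = []
    lat = f.lattice
    for _, row in st.records.iterrows():
        yi = f.years.index(row["year"])
        j = np.argmin(np.linalg.norm(lat - [row["x"], row["y"]], axis=1))
        resid.append(row["value"] - f.values[yi, j])
    assert abs(np.std(resid) - 1.0) < 0.03


def test_gradient_requires_income(geom_small):
    cfg = HazardConfig(name="h", intercept=0.0, matern_sd=1.0, income_gradient=-1.0)
    with pytest.raises(InvalidArgumentError):
        generate_exposure_fields(geom_small, 3, [cfg], seed=0, income=None)


def test_fields_deterministic_under_seed(geom_small):
    cfg = HazardConfig(name="h", intercept=5.0, matern_sd=1.0)
    a = generate_exposure_fields(geom_small, 3, [cfg], seed=11)[0]
    b = generate_exposure_fields(geom_small, 3, [cfg], seed=11)[0]
    np.testing.assert_array_equal(a.values, b.values)


def test_invalid_hazard_configs_rejected():
    with pytest.raises(InvalidArgumentError):
        HazardConfig(name="h", intercept=0.0, matern_range=0.0)
    with pytest.raises(InvalidArgumentError):
        HazardConfig(name="h", intercept=0.0, matern_sd=-1.0)
    with pytest.raises(InvalidArgumentError):
        HazardConfig(name="h", intercept=0.0, temporal_ar=1.0)
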