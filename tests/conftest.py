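import numpy as np
import pandas as pd
import pytest

import envineq as ei
from envineq.synthetic import SimulationTruth, exposure_table


@pytest.fixture(scope="session")
def geom73():
    return ei.generate_geometry(73, seed=1)


@pytest.fixture(scope="session")
def panel73(geom73):
    return ei.generate_covariates(geom73, 8, seed=2)


@pytest.fixture(scope="session")
def income73(panel73):
    return panel73[panel73["sex"] == "male"][["area_id", "year", "income"]]


@pytest.fixture(scope="session")
def geom_small():
    return ei.generate_geometry(16, seed=7)


@pytest.fixture(scope="session")
def exposure73(geom73, income73):
    """One pollutant field plus three noise dayparts, as an areal-truth table."""
    pol = ei.generate_exposure_fields(
        geom73, 8,
        [ei.HazardConfig(name="pollutant", intercept=44.0, matern_sd=5.0,
                         matern_range=0.3, income_gradient=-2.0, temporal_ar=0.8)],
        seed=3, income=income73,
    )
    noi = ei.generate_noise_fields(
        geom73, 8,
        ei.HazardConfig(name="noise", intercept=62.0, matern_sd=4.0,
                        matern_range=0.3, income_gradient=2.0, temporal_ar=0.8),
        seed=4, income=income73,
    )
    return exposure_table(pol + noi, geom73)


@pytest.fixture(scope="session")
def eq1_truth():
    return SimulationTruth(
        coefficients={
            "intercept": np.log(0.01),
            "income_q5": np.log(0.92),
            "pollutant": 0.03,
            "pollutant:q5": np.log(0.85),
            "pop4564_frac": 0.05,
            "pop65_frac": 0.10,
        },
        spec_kwargs={
            "form": "hazard",
            "pollutant": "pollutant",
            "noise": ("noise_daytime", "noise_evening", "noise_night"),
        },
    )


@pytest.fixture(scope="session")
def sim_panel73(panel73, exposure73, eq1_truth, geom73):
    """Panel with deaths simulated from the full generative model."""
    return ei.simulate_deaths(panel73, exposure73, eq1_truth, seed=5, geom=geom73)


@pytest.fixture(scope="session")
def eq1_design(sim_panel73, exposure73, eq1_truth, geom73):
    spec = eq1_truth.model_spec("male")
    return ei.build_design(sim_panel73, exposure73, spec, geom=geom73)


def make_panel(geom, years=2, pop=10_000, income=None, start_year=2007):
    """Minimal hand-built panel for closed-form death-simulation checks."""
    rng = np.random.default_rng(0)
    rows = []
    n = geom.n_areas
    inc = income if income is not None else rng.permutation(np.linspace(50, 200, n))
    for sex in ("male", "female"):
        for t in range(years):
            for k, aid in enumerate(geom.area_ids):
                rows.append({
                    "area_id": aid, "year": start_year + t, "sex": sex,
                    "deaths": 0, "pop": pop,
                    "pop4564_frac": 0.26 + 0.01 * np.sin(k + 1.0),
                    "pop65_frac": 0.21 + 0.01 * np.cos(2.0 * k),
                    "income": float(inc[k]),
                    "foreigners_frac": 0.05, "housing_price": 3200.0,
                    "lu_public_services": 0.11, "lu_industry": 0.05,
                    "lu_roads": 0.27, "lu_urban_parks": 0.15,
                    "lu_forest_parks": 0.06, "density": pop / geom.area_km2[k],
                })
    return pd.DataFrame(rows)
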