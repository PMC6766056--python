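"""Synthetic-city generator.

Produces complete datasets with the statistical structure the downstream
analysis assumes: a polygonal tessellation, a neighborhood-by-year-by-sex
covariate panel whose income index averages 100 across areas each year,
continuous hazard surfaces observed with error at a few point stations,
noise surfaces reported only as 5-dB isoline bands, and Poisson death counts
whose log relative risk follows the same two-level mixed model the fitter
estimates — simulated through the fitter's own design-matrix code path so
the generator and the estimator cannot drift apart.

Default magnitudes are calibrated to a compact European city of ~73
neighborhoods: median population near 20,000 per area (crude death rates
near 90–100 per 10,000 become attainable with a baseline rate of 1%),
income index spanning roughly 35–250 around the city mean of 100, and noise
levels in the high-50s to mid-60s dB with near-identical dispersion across
dayparts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from shapely.geometry import box
from shapely.ops import unary_union

from ._rng import substream
from .design import ModelSpec, build_design
from .errors import InvalidArgumentError, SimulationParameterError
from .geometry import CityGeometry, generate_geometry  # noqa: F401  (re-export)
from .gmrf import matern_gmrf_precision, rw1_sample, sample_gmrf

__all__ = [
    "CovariateConfig",
    "HazardConfig",
    "TrueExposureField",
    "SimulationTruth",
    "StationSeries",
    "NoiseMap",
    "generate_geometry",
    "generate_covariates",
    "generate_exposure_fields",
    "generate_noise_fields",
    "place_stations",
    "make_noise_isolines",
    "simulate_deaths",
    "exposure_table",
]


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CovariateConfig:
    """Tunable knobs of the covariate panel generator."""

    start_year: int = 2007
    pop_median: float = 20_000.0
    pop_log_sd: float = 0.8
    sex_split_male: float = 0.475
    pop4564_mean: float = 0.26
    pop4564_sd: float = 0.02
    pop65_mean: float = 0.21
    pop65_sd: float = 0.04
    pop65_income_corr: float = 0.3
    income_spatial_sd: float = 0.32      # sd of the log-income spatial field
    income_axis_gradient: float = 0.22   # affluence axis across the city
    income_ar: float = 0.95              # year-to-year persistence
    income_innovation_sd: float = 0.05
    housing_rank_corr: float = 0.6
    housing_median: float = 3200.0
    housing_log_sd: float = 0.28
    foreigners_rank_corr: float = -0.6
    foreigners_mean: float = 0.05
    foreigners_logit_sd: float = 0.35
    landuse_base: tuple = (0.11, 0.05, 0.27, 0.15, 0.06, 0.36)  # last = residential
    landuse_concentration: float = 4.0


@dataclass(frozen=True)
class HazardConfig:
    """One hazard surface: mean level, spatial texture and income link."""

    name: str
    intercept: float
    matern_range: float = 0.3
    matern_sd: float = 1.0
    income_gradient: float = 0.0  # slope on standardized income of containing area
    temporal_ar: float = 0.8
    lattice_n: int = 40
    units: str = ""

    def __post_init__(self):
        if self.matern_range <= 0:
            raise InvalidArgumentError("matern_range must be positive")
        if self.matern_sd < 0:
            raise InvalidArgumentError("matern_sd must be nonnegative")
        if not -1.0 < self.temporal_ar < 1.0:
            raise InvalidArgumentError("temporal_ar must lie in (-1, 1)")


# --------------------------------------------------------------------------
# domain types


@dataclass
class TrueExposureField:
    """A hazard's continuous yearly surfaces on a fine lattice."""

    hazard: str
    lattice: np.ndarray          # (K, 2) point coordinates on the unit square
    values: np.ndarray           # (n_years, K) surface values
    years: list
    matern_range: float
    matern_sd: float
    income_gradient: float
    temporal_ar: float
    lattice_n: int

    @property
    def spacing(self) -> float:
        return 1.0 / self.lattice_n

    def area_means(self, geom: CityGeometry) -> pd.DataFrame:
        """Average surface value per (area, year) — the areal-truth table."""
        owner = geom.containing_area(self.lattice)
        rows = []
        for yi, year in enumerate(self.years):
            sums = np.bincount(owner, weights=self.values[yi], minlength=geom.n_areas)
            counts = np.bincount(owner, minlength=geom.n_areas)
            means = sums / np.maximum(counts, 1)
            for k, aid in enumerate(geom.area_ids):
                rows.append({"area_id": aid, "year": year, self.hazard: means[k]})
        return pd.DataFrame(rows)


@dataclass
class StationSeries:
    """Point-support hazard observations: one record per station and year."""

    hazard: str
    records: pd.DataFrame  # columns: station_id, x, y, year, value
    units: str = ""

    def __post_init__(self):
        dup = self.records.duplicated(subset=["station_id", "year"]).any()
        if dup:
            raise InvalidArgumentError("one record per station-year is required")


@dataclass
class NoiseMap:
    """Noise surfaces quantized into half-open decibel bands."""

    daypart: str
    band_width: float
    bands: pd.DataFrame  # columns: year, low_db, high_db, polygon (shapely)


@dataclass
class SimulationTruth:
    """All parameters of the generative death model, plus realized effects."""

    coefficients: dict                      # design column -> value
    spatial_range: float = 0.3
    spatial_sd: float = 0.1
    alpha_sd: float = 0.05
    rw1_sd: float = 0.05
    eta_sd: float = 0.05
    seed: int = 0
    spec_kwargs: dict = field(default_factory=dict)
    realized: dict = field(default_factory=dict)  # sex -> effect vectors

    def model_spec(self, sex: str) -> ModelSpec:
        kwargs = dict(self.spec_kwargs)
        noise = kwargs.pop("noise", ())
        return ModelSpec(sex=sex, noise=tuple(noise), **kwargs)

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "spatial_range": self.spatial_range,
            "spatial_sd": self.spatial_sd,
            "alpha_sd": self.alpha_sd,
            "rw1_sd": self.rw1_sd,
            "eta_sd": self.eta_sd,
            "seed": self.seed,
            "spec_kwargs": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in self.spec_kwargs.items()},
            "realized": {
                sex: {name: np.asarray(vec).tolist() for name, vec in effects.items()}
                for sex, effects in self.realized.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        spec_kwargs = payload.get("spec_kwargs", {})
        if "noise" in spec_kwargs:
            spec_kwargs["noise"] = tuple(spec_kwargs["noise"])
        realized = {
            sex: {name: np.asarray(vec) for name, vec in effects.items()}
            for sex, effects in payload.get("realized", {}).items()
        }
        return cls(
            coefficients=payload["coefficients"],
            spatial_range=payload["spatial_range"],
            spatial_sd=payload["spatial_sd"],
            alpha_sd=payload["alpha_sd"],
            rw1_sd=payload["rw1_sd"],
            eta_sd=payload["eta_sd"],
            seed=payload["seed"],
            spec_kwargs=spec_kwargs,
            realized=realized,
        )


# --------------------------------------------------------------------------
# covariate panel


def _gaussian_copula(z_ref: np.ndarray, corr: float, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal scores with the requested correlation to z_ref."""
    eps = rng.standard_normal(z_ref.shape)
    return corr * z_ref + math.sqrt(max(0.0, 1.0 - corr**2)) * eps


def generate_covariates(
    geom: CityGeometry,
    years: int,
    config: Optional[CovariateConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format covariate panel: one row per (area, year, sex).

    Income is a spatially smooth log-normal field with an affluence axis,
    rescaled so the across-area mean each year is exactly 100.  Housing
    prices and the foreigners share are tied to income through a Gaussian
    copula with the configured correlations; land-use shares come from a
    Dirichlet whose sixth (residential) component is dropped so the five
    reported shares sum to at most one.  Death counts are zero-initialised;
    :func:`simulate_deaths` fills them.
    """
    if years < 2:
        raise InvalidArgumentError("need at least 2 years (the RW1 trend needs >= 2)")
    cfg = config or CovariateConfig()
    rng = substream(seed, "covariates")
    n = geom.n_areas
    year_labels = [cfg.start_year + k for k in range(years)]

    # smooth log-income field with an affluence axis, AR(1) over years
    q = matern_gmrf_precision(geom, 0.4, max(cfg.income_spatial_sd, 1e-9))
    base = sample_gmrf(q, rng) if cfg.income_spatial_sd > 0 else np.zeros(n)
    axis = geom.centroids @ np.array([1.0, 0.6])
    axis = (axis - axis.mean()) / max(axis.std(), 1e-12)
    log_inc = np.empty((years, n))
    current = base + cfg.income_axis_gradient * axis
    for yi in range(years):
        if yi > 0:
            innov = rng.normal(0.0, cfg.income_innovation_sd, size=n)
            current = cfg.income_ar * current + math.sqrt(1 - cfg.income_ar**2) * innov + \
                (1 - cfg.income_ar) * (base + cfg.income_axis_gradient * axis)
        log_inc[yi] = current
    income = np.exp(log_inc)
    income = 100.0 * income / income.mean(axis=1, keepdims=True)

    z_inc = (log_inc - log_inc.mean()) / max(log_inc.std(), 1e-12)
    z_house = _gaussian_copula(z_inc, cfg.housing_rank_corr, rng)
    housing = cfg.housing_median * np.exp(cfg.housing_log_sd * z_house)

    # land use constant over years per area
    alpha = cfg.landuse_concentration * np.asarray(cfg.landuse_base)
    landuse = rng.dirichlet(alpha, size=n)[:, :5]

    pop_area = cfg.pop_median * np.exp(rng.normal(0.0, cfg.pop_log_sd, size=n))
    growth = rng.normal(0.002, 0.004, size=(years, n)).cumsum(axis=0)
    z65 = _gaussian_copula(z_inc.mean(axis=0), cfg.pop65_income_corr, rng)

    rows = []
    for sex in ("male", "female"):
        frac = cfg.sex_split_male if sex == "male" else 1.0 - cfg.sex_split_male
        z_for = _gaussian_copula(z_inc, cfg.foreigners_rank_corr, rng)
        foreigners = expit(logit(cfg.foreigners_mean) + cfg.foreigners_logit_sd * z_for)
        p4564 = np.clip(rng.normal(cfg.pop4564_mean, cfg.pop4564_sd, size=(years, n)), 0.05, 0.6)
        p65 = np.clip(
            cfg.pop65_mean + cfg.pop65_sd * (0.7 * z65[None, :] + 0.7 * rng.standard_normal((years, n))),
            0.05, 0.6,
        )
        p65 = np.minimum(p65, 0.95 - p4564)
        for yi, year in enumerate(year_labels):
            pop = np.maximum((pop_area * frac * np.exp(growth[yi])).round(), 10).astype(int)
            for k, aid in enumerate(geom.area_ids):
                rows.append(
                    {
                        "area_id": aid,
                        "year": year,
                        "sex": sex,
                        "deaths": 0,
                        "pop": int(pop[k]),
                        "pop4564_frac": float(p4564[yi, k]),
                        "pop65_frac": float(p65[yi, k]),
                        "income": float(income[yi, k]),
                        "foreigners_frac": float(foreigners[yi, k]),
                        "housing_price": float(housing[yi, k]),
                        "lu_public_services": float(landuse[k, 0]),
                        "lu_industry": float(landuse[k, 1]),
                        "lu_roads": float(landuse[k, 2]),
                        "lu_urban_parks": float(landuse[k, 3]),
                        "lu_forest_parks": float(landuse[k, 4]),
                        "density": float(pop[k] / geom.area_km2[k]),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# hazard surfaces


def _matern32_cov(pts: np.ndarray, rho: float, sd: float) -> np.ndarray:
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    s = math.sqrt(3.0) * d / rho
    return sd**2 * (1.0 + s) * np.exp(-s)


def _lattice(nl: int) -> np.ndarray:
    h = 1.0 / nl
    xs = (np.arange(nl) + 0.5) * h
    gx, gy = np.meshgrid(xs, xs)
    return np.column_stack([gx.ravel(), gy.ravel()])


def generate_exposure_fields(
    geom: CityGeometry,
    years,
    hazard_configs,
    seed: int = 0,
    income: Optional[pd.DataFrame] = None,
) -> list:
    """Yearly Matern surfaces per hazard with AR(1) innovation sharing.

    Each surface is intercept + income_gradient * standardized income of the
    containing area + a Matern(3/2) Gaussian field; consecutive years share
    innovations through an AR(1) with coefficient ``temporal_ar``.

    ``income`` is a table with columns (area_id, year, income); it is
    required whenever any hazard has a nonzero income gradient.
    """
    if isinstance(years, int):
        year_labels = [CovariateConfig().start_year + k for k in range(years)]
    else:
        year_labels = list(years)
    fields = []
    for cfg in hazard_configs:
        rng = substream(seed, f"field-{cfg.name}")
        pts = _lattice(cfg.lattice_n)
        owner = geom.containing_area(pts)
        mean = np.full((len(year_labels), len(pts)), float(cfg.intercept))
        if cfg.income_gradient != 0.0:
            if income is None:
                raise InvalidArgumentError(
                    f"hazard {cfg.name!r} has an income gradient but no income table was given"
                )
            for yi, year in enumerate(year_labels):
                sub = income[income["year"] == year].set_index("area_id")["income"]
                vals = sub.reindex(geom.area_ids).to_numpy(dtype=float)
                z = (vals - vals.mean()) / max(vals.std(), 1e-12)
                mean[yi] += cfg.income_gradient * z[owner]
        if cfg.matern_sd > 0:
            cov = _matern32_cov(pts, cfg.matern_range, cfg.matern_sd)
            cov[np.diag_indices_from(cov)] += 1e-10
            chol = np.linalg.cholesky(cov)
            dev = np.empty_like(mean)
            current = chol @ rng.standard_normal(len(pts))
            dev[0] = current
            for yi in range(1, len(year_labels)):
                innov = chol @ rng.standard_normal(len(pts))
                current = cfg.temporal_ar * current + math.sqrt(1 - cfg.temporal_ar**2) * innov
                dev[yi] = current
            values = mean + dev
        else:
            values = mean
        fields.append(
            TrueExposureField(
                hazard=cfg.name,
                lattice=pts,
                values=values,
                years=year_labels,
                matern_range=cfg.matern_range,
                matern_sd=cfg.matern_sd,
                income_gradient=cfg.income_gradient,
                temporal_ar=cfg.temporal_ar,
                lattice_n=cfg.lattice_n,
            )
        )
    return fields


_DAYPART_OFFSETS = {"daytime": 0.0, "evening": -1.5, "night": -7.5}


def generate_noise_fields(
    geom: CityGeometry,
    years,
    base_config: HazardConfig,
    seed: int = 0,
    income: Optional[pd.DataFrame] = None,
    daypart_jitter: float = 0.3,
) -> list:
    """Three daypart noise surfaces: one shared base field plus offsets.

    Mirrors strategic noise maps where the daytime, evening and night
    surfaces differ mostly by a level shift and show near-identical
    dispersions.  Each daypart additionally receives an independent Matern
    deviation with sd ``daypart_jitter * matern_sd`` (same range and
    temporal structure) so the three surfaces are strongly but not
    perfectly correlated — exact collinearity would leave the daypart
    coefficients of the health model unidentified.
    """
    base = generate_exposure_fields(geom, years, [base_config], seed=seed, income=income)[0]
    fields = []
    for daypart, offset in _DAYPART_OFFSETS.items():
        values = base.values + offset
        if daypart_jitter > 0 and base_config.matern_sd > 0:
            dev_cfg = HazardConfig(
                name=f"{base_config.name}_{daypart}_dev",
                intercept=0.0,
                matern_range=base_config.matern_range,
                matern_sd=daypart_jitter * base_config.matern_sd,
                income_gradient=0.0,
                temporal_ar=base_config.temporal_ar,
                lattice_n=base_config.lattice_n,
            )
            dev = generate_exposure_fields(geom, years, [dev_cfg], seed=seed)[0]
            values = values + dev.values
        fields.append(
            TrueExposureField(
                hazard=f"noise_{daypart}",
                lattice=base.lattice,
                values=values,
                years=base.years,
                matern_range=base.matern_range,
                matern_sd=base.matern_sd,
                income_gradient=base.income_gradient,
                temporal_ar=base.temporal_ar,
                lattice_n=base.lattice_n,
            )
        )
    return fields


def place_stations(
    field: TrueExposureField,
    n_stations: int,
    obs_sd: float,
    seed: int = 0,
) -> StationSeries:
    """Observe the surface at fixed random lattice points with iid error."""
    if not 1 <= n_stations <= len(field.lattice):
        raise InvalidArgumentError("n_stations must lie in [1, lattice size]")
    if obs_sd < 0:
        raise InvalidArgumentError("obs_sd must be nonnegative")
    rng = substream(seed, f"stations-{field.hazard}")
    idx = np.sort(rng.choice(len(field.lattice), size=n_stations, replace=False))
    rows = []
    for yi, year in enumerate(field.years):
        noise = rng.normal(0.0, obs_sd, size=n_stations) if obs_sd > 0 else np.zeros(n_stations)
        for k, j in enumerate(idx):
            rows.append(
                {
                    "station_id": int(k + 1),
                    "x": float(field.lattice[j, 0]),
                    "y": float(field.lattice[j, 1]),
                    "year": year,
                    "value": float(field.values[yi, j] + noise[k]),
                }
            )
    return StationSeries(hazard=field.hazard, records=pd.DataFrame(rows))


def make_noise_isolines(field: TrueExposureField, band_db: float = 5.0) -> NoiseMap:
    """Quantize a surface into half-open [k*band, (k+1)*band) polygon bands."""
    if band_db <= 0:
        raise InvalidArgumentError("band_db must be positive")
    h = field.spacing
    daypart = field.hazard.removeprefix("noise_") if field.hazard.startswith("noise_") else field.hazard
    rows = []
    for yi, year in enumerate(field.years):
        band_idx = np.floor(field.values[yi] / band_db).astype(int)
        for k in np.unique(band_idx):
            cells = field.lattice[band_idx == k]
            poly = unary_union(
                [box(x - h / 2, y - h / 2, x + h / 2, y + h / 2) for x, y in cells]
            )
            rows.append(
                {
                    "year": year,
                    "low_db": float(k * band_db),
                    "high_db": float((k + 1) * band_db),
                    "polygon": poly,
                }
            )
    return NoiseMap(daypart=daypart, band_width=float(band_db), bands=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# death simulation


def exposure_table(fields, geom: CityGeometry) -> pd.DataFrame:
    """Merge per-hazard areal truth tables into one (area_id, year) table."""
    out = None
    for f in fields:
        t = f.area_means(geom)
        out = t if out is None else out.merge(t, on=["area_id", "year"])
    return out


def simulate_deaths(
    panel: pd.DataFrame,
    area_exposures: Optional[pd.DataFrame],
    truth: SimulationTruth,
    seed: int = 0,
    geom: Optional[CityGeometry] = None,
) -> pd.DataFrame:
    """Fill the panel's death counts from the generative two-level model.

    The linear predictor is computed through the fitter's own design matrix
    (same quintile, standardisation and interaction definitions), random
    effects are drawn from their priors at the truth's hyperparameters, and
    deaths are Poisson with mean mu_it * Pop_it.
    """
    out = panel.copy()
    realized: dict = {}
    for sex in sorted(out["sex"].unique()):
        spec = truth.model_spec(sex)
        design = build_design(out, area_exposures, spec, geom=geom)
        beta = design.coefficient_vector(truth.coefficients)
        rng = substream(seed, f"deaths-{sex}")
        n_a, n_t = len(design.area_ids), len(design.years)
        if truth.spatial_sd > 0:
            if geom is None:
                raise InvalidArgumentError("spatial effect requires geometry")
            q = matern_gmrf_precision(geom, truth.spatial_range, truth.spatial_sd)
            s_eff = sample_gmrf(q, rng)
        else:
            s_eff = np.zeros(n_a)
        alpha = rng.normal(0.0, truth.alpha_sd, size=n_a) if truth.alpha_sd > 0 else np.zeros(n_a)
        t_eff = rw1_sample(n_t, truth.rw1_sd, rng) if truth.rw1_sd > 0 else np.zeros(n_t)
        eta = rng.normal(0.0, truth.eta_sd, size=design.n_obs) if truth.eta_sd > 0 else np.zeros(design.n_obs)
        log_mu = (
            design.X @ beta
            + s_eff[design.area_index]
            + alpha[design.area_index]
            + t_eff[design.year_index]
            + eta
        )
        mean = np.exp(log_mu + design.offset)
        if np.any(~np.isfinite(mean)) or mean.max() > 1e9:
            raise SimulationParameterError(
                f"Poisson mean overflows (max {np.nanmax(mean):.3g}); check coefficients"
            )
        deaths = rng.poisson(mean)
        key = pd.MultiIndex.from_arrays([out["area_id"], out["year"]])
        lookup = pd.Series(deaths, index=design.index)
        mask = out["sex"] == sex
        out.loc[mask, "deaths"] = lookup.reindex(key[mask]).to_numpy()
        realized[sex] = {
            "spatial": s_eff, "iid_area": alpha, "rw1": t_eff, "interaction": eta,
            "log_mu": log_mu,
        }
    truth.realized = realized
    truth.seed = seed
    return out
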