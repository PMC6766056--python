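"""Model specification and design-matrix construction.

One code path builds the fixed-effect matrix for both the simulator and the
fitter, so simulated death counts and fitted models share an identical
definition of every column — quintile dummies, standardisation, interactions
and the population offset.

Two model forms are supported:

``hazard``
    The full ecological regression: income-quintile dummies, one pollutant,
    three noise dayparts, six land-use covariates, foreigners share, housing
    prices, the two age-structure regressors, and quintile interactions with
    the pollutant and each noise daypart.

``polluted``
    The summary regression: a binary polluted-neighborhood indicator, its
    quintile interactions, plus housing prices, land use and age structure.

Continuous covariates are z-scored with the scalers stored on the bundle, so
reported relative risks can be mapped back to the original units.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError, QuintileError, SchemaError
from .priors import LogNormalPrior, PCPrior
from .quintiles import QuintileAssignment, yearly_quintiles

__all__ = [
    "LAND_USE_COLS",
    "RandomEffects",
    "ModelSpec",
    "DesignBundle",
    "build_design",
]

LAND_USE_COLS = (
    "lu_public_services",
    "lu_industry",
    "lu_roads",
    "lu_urban_parks",
    "lu_forest_parks",
    "density",
)

_BASE_PANEL_COLS = ("area_id", "year", "sex", "deaths", "pop")


@dataclass(frozen=True)
class RandomEffects:
    """Which latent components enter the linear predictor."""

    spatial: bool = True       # Matern GMRF over areas
    iid_area: bool = True      # unstructured area heterogeneity
    rw1: bool = True           # first-order random-walk trend over years
    interaction: bool = True   # iid area-year interaction

    def any(self) -> bool:
        return self.spatial or self.iid_area or self.rw1 or self.interaction


def _default_pc_priors() -> dict:
    return {
        "spatial": PCPrior(1.0, 0.01),
        "iid_area": PCPrior(1.0, 0.01),
        "rw1": PCPrior(1.0, 0.01),
        "interaction": PCPrior(1.0, 0.01),
    }


@dataclass(frozen=True)
class ModelSpec:
    """Everything needed to build and fit one sex-stratified model."""

    sex: str = "male"
    form: str = "hazard"  # "hazard" (full) or "polluted" (summary)
    pollutant: Optional[str] = None
    noise: tuple = ()
    include_foreigners: bool = True
    include_housing: bool = True
    include_age: bool = True
    include_land_use: bool = True
    pollutant_quintile_interaction: bool = True
    noise_quintile_interaction: bool = True
    polluted_quintile_interaction: bool = True
    random_effects: RandomEffects = RandomEffects()
    pc_priors: dict = field(default_factory=_default_pc_priors)
    range_prior: LogNormalPrior = LogNormalPrior(0.3, 1.0)
    method: str = "laplace"
    cred_levels: tuple = (0.90, 0.95)
    fixed_effect_precision: float = 1e-6
    max_opt_evals: int = 150
    mcmc_iterations: int = 4000
    mcmc_burn: int = 2000
    strict: bool = False

    def __post_init__(self):
        if self.form not in ("hazard", "polluted"):
            raise SchemaError(f"unknown model form {self.form!r}")
        if self.form == "polluted" and (self.pollutant or self.noise):
            raise SchemaError("the summary form uses only the polluted indicator")
        if self.method not in ("laplace", "mcmc"):
            raise SchemaError(f"unknown inference method {self.method!r}")

    def without_random_effects(self) -> "ModelSpec":
        return replace(self, random_effects=RandomEffects(False, False, False, False))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"] = list(self.noise)
        d["cred_levels"] = list(self.cred_levels)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelSpec":
        d = dict(payload)
        if "random_effects" in d:
            d["random_effects"] = RandomEffects(**d["random_effects"])
        if "pc_priors" in d:
            d["pc_priors"] = {k: PCPrior(**v) for k, v in d["pc_priors"].items()}
        if "range_prior" in d:
            d["range_prior"] = LogNormalPrior(**d["range_prior"])
        if "noise" in d:
            d["noise"] = tuple(d["noise"])
        if "cred_levels" in d:
            d["cred_levels"] = tuple(d["cred_levels"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DesignBundle:
    """Fixed-effect matrix, offset and random-effect index maps for one fit."""

    X: np.ndarray
    columns: list[str]
    scalers: dict  # column -> (mean, sd) for standardized columns
    y: np.ndarray
    offset: np.ndarray
    area_index: np.ndarray  # 0-based, into area_ids order
    year_index: np.ndarray  # 0-based, into years order
    area_ids: list[int]
    years: list[int]
    quintiles: QuintileAssignment
    index: pd.MultiIndex  # (area_id, year) row index
    spec: ModelSpec
    geom: object = None  # CityGeometry, required when spatial effect is on

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Exportable view of the design for external cross-checks."""
        df = pd.DataFrame(self.X, columns=self.columns, index=self.index)
        df.insert(0, "deaths", self.y)
        df.insert(1, "log_pop_offset", self.offset)
        return df

    def coefficient_vector(self, coefficients: dict) -> np.ndarray:
        """Dense coefficient vector from a {column: value} mapping."""
        unknown = set(coefficients) - set(self.columns)
        if unknown:
            raise SchemaError(f"coefficients for unknown columns: {sorted(unknown)}")
        return np.array([float(coefficients.get(c, 0.0)) for c in self.columns])


def _standardize(values: np.ndarray, scalers: dict, name: str, fixed: Optional[dict]) -> np.ndarray:
    if fixed is not None and name in fixed:
        mu, sd = fixed[name]
    else:
        mu = float(np.mean(values))
        sd = float(np.std(values))
    if sd == 0:
        raise SchemaError(f"covariate {name!r} is constant; cannot standardize")
    scalers[name] = (mu, sd)
    return (values - mu) / sd


def build_design(
    panel: pd.DataFrame,
    exposures: Optional[pd.DataFrame],
    spec: ModelSpec,
    geom=None,
    fixed_scalers: Optional[dict] = None,
) -> DesignBundle:
    """Assemble the fixed-effect matrix, offset and index maps.

    Parameters
    ----------
    panel
        Long-format covariate panel (one row per area, year and sex).
    exposures
        Table keyed by (area_id, year) holding the hazard columns the spec
        references (pollutant, noise dayparts, or the ``polluted`` indicator).
    spec
        Model specification; only rows of ``spec.sex`` are used.
    geom
        City geometry; required later by the fitter when the spatial effect
        is active, carried on the bundle for convenience.
    fixed_scalers
        Standardisation (mean, sd) pairs to reuse instead of recomputing —
        keeps coefficients comparable when the same model is refitted on
        multiple exposure draws.
    """
    required = set(_BASE_PANEL_COLS) | {"income"}
    if spec.include_foreigners:
        required.add("foreigners_frac")
    if spec.include_housing:
        required.add("housing_price")
    if spec.include_age:
        required.update(("pop4564_frac", "pop65_frac"))
    if spec.include_land_use:
        required.update(LAND_USE_COLS)
    missing = sorted(required - set(panel.columns))
    if missing:
        raise SchemaError(f"panel is missing columns: {missing}")

    df = panel[panel["sex"] == spec.sex].copy()
    if df.empty:
        raise SchemaError(f"panel has no rows for sex {spec.sex!r}")
    df = df.sort_values(["area_id", "year"]).reset_index(drop=True)

    hazard_cols = []
    if spec.form == "hazard":
        if spec.pollutant:
            hazard_cols.append(spec.pollutant)
        hazard_cols.extend(spec.noise)
    else:
        hazard_cols.append("polluted")
    if hazard_cols:
        if exposures is None:
            raise AlignmentError("spec references hazards but no exposure table given")
        missing = sorted(set(hazard_cols) - set(exposures.columns))
        if missing:
            raise SchemaError(f"exposure table is missing columns: {missing}")
        merged = df.merge(
            exposures[["area_id", "year", *hazard_cols]],
            on=["area_id", "year"],
            how="left",
            validate="one_to_one",
        )
        if merged[hazard_cols].isna().any().any():
            raise AlignmentError("exposure table does not cover every (area, year)")
        df = merged

    index = pd.MultiIndex.from_arrays(
        [df["area_id"], df["year"]], names=["area_id", "year"]
    )
    for year, grp in df.groupby("year"):
        if len(grp) < 5:
            raise QuintileError(f"year {year} has {len(grp)} areas; quintiles need >= 5")
    quintiles = yearly_quintiles(pd.Series(df["income"].to_numpy(), index=index))
    qlab = quintiles.labels.to_numpy()

    scalers: dict = {}
    cols: list[str] = []
    mats: list[np.ndarray] = []

    def add(name, values):
        cols.append(name)
        mats.append(np.asarray(values, dtype=float))

    add("intercept", np.ones(len(df)))
    qdum = {}
    for q in range(2, 6):
        qdum[q] = (qlab == q).astype(float)
        add(f"income_q{q}", qdum[q])

    if spec.form == "hazard":
        if spec.pollutant:
            z = _standardize(df[spec.pollutant].to_numpy(), scalers, spec.pollutant, fixed_scalers)
            add(spec.pollutant, z)
        for col in spec.noise:
            z = _standardize(df[col].to_numpy(), scalers, col, fixed_scalers)
            add(col, z)
    else:
        add("polluted", df["polluted"].to_numpy())

    if spec.include_foreigners:
        add("foreigners_frac",
            _standardize(df["foreigners_frac"].to_numpy(), scalers, "foreigners_frac", fixed_scalers))
    if spec.include_housing:
        add("housing_price",
            _standardize(df["housing_price"].to_numpy(), scalers, "housing_price", fixed_scalers))
    if spec.include_land_use:
        for col in LAND_USE_COLS:
            add(col, _standardize(df[col].to_numpy(), scalers, col, fixed_scalers))

    def add_interactions(base_name, base_values):
        for q in range(2, 6):
            add(f"{base_name}:q{q}", base_values * qdum[q])

    if spec.form == "hazard":
        if spec.pollutant and spec.pollutant_quintile_interaction:
            col_idx = cols.index(spec.pollutant)
            add_interactions(spec.pollutant, mats[col_idx])
        if spec.noise_quintile_interaction:
            for col in spec.noise:
                add_interactions(col, mats[cols.index(col)])
    elif spec.polluted_quintile_interaction:
        add_interactions("polluted", mats[cols.index("polluted")])

    if spec.include_age:
        add("pop4564_frac",
            _standardize(df["pop4564_frac"].to_numpy(), scalers, "pop4564_frac", fixed_scalers))
        add("pop65_frac",
            _standardize(df["pop65_frac"].to_numpy(), scalers, "pop65_frac", fixed_scalers))

    X = np.column_stack(mats)
    pops = df["pop"].to_numpy(dtype=float)
    if np.any(pops <= 0):
        raise SchemaError("population must be positive for the offset")

    area_ids = list(geom.area_ids) if geom is not None else sorted(df["area_id"].unique())
    years = sorted(df["year"].unique())
    apos = {a: k for k, a in enumerate(area_ids)}
    ypos = {y: k for k, y in enumerate(years)}
    try:
        area_index = df["area_id"].map(apos).to_numpy(dtype=int)
    except (TypeError, ValueError) as exc:
        raise AlignmentError("panel areas not present in geometry") from exc
    year_index = df["year"].map(ypos).to_numpy(dtype=int)

    return DesignBundle(
        X=X,
        columns=cols,
        scalers=scalers,
        y=df["deaths"].to_numpy(dtype=float),
        offset=np.log(pops),
        area_index=area_index,
        year_index=year_index,
        area_ids=area_ids,
        years=years,
        quintiles=quintiles,
        index=index,
        spec=spec,
        geom=geom,
    )
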