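"""On-disk formats: GeoJSON geometry and noise bands, CSV panels and tables.

All artifacts are plain text so a real city's data can be substituted for
the synthetic one: geometry as a GeoJSON FeatureCollection with an
``area_id`` property, the covariate panel as a long-format CSV with a fixed
documented header, station records and exposure posteriors as CSV, model
truth and provenance as JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.polygon import orient

from .errors import FormatError, SchemaError
from .geometry import DOMAIN_KM2, CityGeometry
from .synthetic import NoiseMap, StationSeries

logger = logging.getLogger("envineq")

__all__ = [
    "PANEL_COLUMNS",
    "read_geometry",
    "write_geometry",
    "read_panel",
    "write_panel",
    "read_stations",
    "write_stations",
    "write_noise_map",
    "read_noise_map",
    "write_exposure_posterior",
    "RunConfig",
    "provenance_record",
]

PANEL_COLUMNS = (
    "area_id", "year", "sex", "deaths", "pop",
    "pop4564_frac", "pop65_frac", "income", "foreigners_frac", "housing_price",
    "lu_public_services", "lu_industry", "lu_roads", "lu_urban_parks",
    "lu_forest_parks", "density",
)

_FRACTION_COLS = ("pop4564_frac", "pop65_frac", "foreigners_frac",
                  "lu_public_services", "lu_industry", "lu_roads",
                  "lu_urban_parks", "lu_forest_parks")


# --------------------------------------------------------------------------
# geometry


def write_geometry(geom: CityGeometry, path) -> None:
    features = []
    for k, aid in enumerate(geom.area_ids):
        features.append(
            {
                "type": "Feature",
                "properties": {"area_id": int(aid)},
                "geometry": mapping(orient(geom.polygons[k])),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geometry(path) -> CityGeometry:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("type") != "FeatureCollection":
        raise FormatError("geometry file is not a GeoJSON FeatureCollection")
    ids, polys = [], []
    for k, feat in enumerate(payload.get("features", [])):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise FormatError(f"feature {k} is missing the area_id property")
        try:
            poly = shape(feat["geometry"])
        except Exception as exc:
            raise FormatError(f"feature {k}: invalid geometry ({exc})") from exc
        if poly.geom_type != "Polygon" or not poly.is_valid:
            raise FormatError(f"feature {k}: expected a valid Polygon ring")
        if not poly.exterior.is_ccw:
            logger.warning("feature %d: exterior ring not counter-clockwise; normalizing", k)
            poly = orient(poly)
        ids.append(int(props["area_id"]))
        polys.append(poly)
    if not ids:
        raise FormatError("geometry file holds no polygon features")
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    area = np.array([p.area for p in polys])
    neighbors = {a: set() for a in ids}
    import shapely as _sh

    tree = _sh.STRtree(polys)
    ii, jj = tree.query(polys, predicate="intersects")
    for i, j in zip(ii, jj):
        if i < j and polys[i].intersection(polys[j]).length > 1e-9:
            neighbors[ids[i]].add(ids[j])
            neighbors[ids[j]].add(ids[i])
    return CityGeometry(
        area_ids=ids, polygons=polys, centroids=centroids,
        neighbors=neighbors, area_km2=area * DOMAIN_KM2,
    )


# --------------------------------------------------------------------------
# covariate panel


def write_panel(panel: pd.DataFrame, path) -> None:
    missing = sorted(set(PANEL_COLUMNS) - set(panel.columns))
    if missing:
        raise SchemaError(f"panel is missing columns: {missing}")
    panel[list(PANEL_COLUMNS)].to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = sorted(set(PANEL_COLUMNS) - set(df.columns))
    if missing:
        raise SchemaError(f"panel is missing columns: {missing}")
    dup = df.duplicated(subset=["area_id", "year", "sex"])
    if dup.any():
        raise SchemaError(f"duplicate (area, year, sex) rows: {list(df.index[dup])[:10]}")
    bad = df.index[df["deaths"] > df["pop"]]
    if len(bad):
        raise SchemaError(f"deaths exceed population at rows: {list(bad)[:10]}")
    for col in _FRACTION_COLS:
        out = df.index[(df[col] < 0) | (df[col] > 1)]
        if len(out):
            raise SchemaError(f"column {col} outside [0, 1] at rows: {list(out)[:10]}")
    years = np.sort(df["year"].unique())
    if len(years) > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
        raise SchemaError("years do not form a contiguous range")
    expected = len(df["area_id"].unique()) * len(years) * len(df["sex"].unique())
    if len(df) != expected:
        counts = df.groupby(["area_id", "sex"])["year"].nunique()
        short = counts[counts < len(years)]
        raise SchemaError(
            f"panel incomplete: expected {expected} rows, got {len(df)}"
            + (f"; short areas: {list(short.index[:5])}" if len(short) else "")
        )
    return df


# --------------------------------------------------------------------------
# stations, noise, exposure posteriors


def write_stations(stations: StationSeries, path) -> None:
    df = stations.records.copy()
    df.insert(0, "hazard", stations.hazard)
    df.to_csv(path, index=False)


def read_stations(path) -> list:
    df = pd.read_csv(path)
    required = {"hazard", "station_id", "x", "y", "year", "value"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"station file is missing columns: {missing}")
    out = []
    for hazard, sub in df.groupby("hazard"):
        out.append(StationSeries(hazard=hazard, records=sub.drop(columns="hazard").reset_index(drop=True)))
    return out


def write_noise_map(noisemap: NoiseMap, path) -> None:
    features = []
    for _, row in noisemap.bands.iterrows():
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "year": int(row["year"]),
                    "daypart": noisemap.daypart,
                    "band_low_db": float(row["low_db"]),
                    "band_high_db": float(row["high_db"]),
                },
                "geometry": mapping(row["polygon"]),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_noise_map(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("type") != "FeatureCollection":
        raise FormatError("noise map is not a GeoJSON FeatureCollection")
    rows = []
    for k, feat in enumerate(payload.get("features", [])):
        props = feat.get("properties") or {}
        for key in ("year", "daypart", "band_low_db", "band_high_db"):
            if key not in props:
                raise FormatError(f"noise feature {k} is missing property {key!r}")
        rows.append(
            {
                "daypart": props["daypart"],
                "year": int(props["year"]),
                "low_db": float(props["band_low_db"]),
                "high_db": float(props["band_high_db"]),
                "polygon": shape(feat["geometry"]),
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for daypart, sub in df.groupby("daypart"):
        widths = (sub["high_db"] - sub["low_db"]).round(9).unique()
        if len(widths) != 1:
            raise FormatError(f"daypart {daypart}: inconsistent band widths {widths}")
        out.append(NoiseMap(daypart=daypart, band_width=float(widths[0]),
                            bands=sub.drop(columns="daypart").reset_index(drop=True)))
    return out


def write_exposure_posterior(post, path, draws_path=None) -> None:
    df = post.table.copy()
    df.insert(0, "hazard", post.hazard)
    df["provenance"] = post.provenance
    df.to_csv(path, index=False)
    if draws_path is not None and post.draws is not None:
        np.savetxt(draws_path, post.draws, delimiter=",")


# --------------------------------------------------------------------------
# run configuration and provenance


@dataclass
class RunConfig:
    """Paths, seed and stage settings for a CLI-driven run."""

    seed: int = 1
    output_dir: str = "envineq-run"
    n_areas: int = 73
    years: int = 8
    sex: str = "male"
    m_draws: int = 20
    quintile_rule: str = "all"
    strict: bool = False
    geometry_path: Optional[str] = None
    panel_path: Optional[str] = None
    stations_path: Optional[str] = None
    noise_path: Optional[str] = None
    hazards: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.__dict__, sort_keys=True).encode("utf8")
        ).hexdigest()[:16]


def provenance_record(config: RunConfig, stage: str, outputs: list) -> dict:
    import envineq

    return {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.digest(),
        "package_version": envineq.__version__,
        "outputs": [str(Path(p)) for p in outputs],
    }
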