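import math

import numpy as np
import pytest
from shapely.geometry import box

import envineq as ei
from envineq.errors import PartialCoverageError
from envineq.exposure import noise_to_areas
from envineq.synthetic import (
    HazardConfig,
    NoiseMap,
    TrueExposureField,
    generate_exposure_fields,
    make_noise_isolines,
)


def field_from_values(values, lattice_n=20, hazard="noise_daytime"):
    h = 1.0 / lattice_n
    xs = (np.arange(lattice_n) + 0.5) * h
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = np.broadcast_to(values, (1, lattice_n * lattice_n)).copy()
    return TrueExposureField(hazard=hazard, lattice=pts, values=vals, years=[2007],
                             matern_range=0.3, matern_sd=0.0, income_gradient=0.0,
                             temporal_ar=0.0, lattice_n=lattice_n)


def test_constant_surface_gives_single_covering_band():
    nm = make_noise_isolines(field_from_values(62.1), band_db=5.0)
    assert len(nm.bands) == 1
    row = nm.bands.iloc[0]
    assert (row["low_db"], row["high_db"]) == (60.0, 65.0)
    assert row["polygon"].area == pytest.approx(1.0, abs=1e-9)


def test_quantization_bound_half_band(geom_small):
    """Reconstructing from band midpoints is within band/2 of the truth."""
    cfg = HazardConfig(name="noise_daytime", intercept=60.0, matern_sd=4.0,
                       matern_range=0.3, lattice_n=20)
    f = generate_exposure_fields(geom_small, 2, [cfg], seed=1)[0]
    nm = make_noise_isolines(f, band_db=5.0)
    for yi, year in enumerate(f.years):
        sub = nm.bands[nm.bands["year"] == year]
        mids = np.full(len(f.lattice), np.nan)
        import shapely

        pts = shapely.points(f.lattice)
        for _, row in sub.iterrows():
            inside = shapely.covers(row["polygon"], pts)
            mids[inside] = 0.5 * (row["low_db"] + row["high_db"])
        assert np.all(np.abs(mids - f.values[yi]) <= 2.5 + 1e-9)


def test_linear_ramp_band_count():
    n = 20
    ramp = np.repeat(np.linspace(0.0, 79.0, n), n)  # rows sweep 0..79
    nm = make_noise_isolines(field_from_values(ramp, lattice_n=n), band_db=5.0)
    assert len(nm.bands) == math.ceil(79.0 / 5.0)


def test_single_band_area_uniform_moments(geom_small):
    nm = make_noise_isolines(field_from_values(62.1), band_db=5.0)
    post = noise_to_areas(nm, geom_small)
    assert np.allclose(post.table["mean"], 62.5)
    assert np.allclose(post.table["sd"], 5.0 / math.sqrt(12.0), atol=1e-9)


def make_two_band_map(split=0.5):
    bands = [
        {"year": 2007, "low_db": 55.0, "high_db": 60.0, "polygon": box(0, 0, split, 1)},
        {"year": 2007, "low_db": 60.0, "high_db": 65.0, "polygon": box(split, 0, 1, 1)},
    ]
    import pandas as pd

    return NoiseMap(daypart="daytime", band_width=5.0, bands=pd.DataFrame(bands))


def test_even_split_mean_is_shared_boundary(geom_small):
    # aggregate over the whole square: a single-area geometry
    geom = ei.generate_geometry(4, seed=0)
    nm = make_two_band_map(0.5)
    post = noise_to_areas(nm, geom)
    total_area = np.array([p.area for p in geom.polygons])
    overall = float(np.average(post.table["mean"], weights=total_area))
    assert overall == pytest.approx(60.0, abs=1e-9)


def test_three_band_weighted_midpoint_oracle():
    """Hand-computed mixture for weights 0.2/0.3/0.5 on three 5-dB bands."""
    import pandas as pd

    bands = [
        {"year": 2007, "low_db": 50.0, "high_db": 55.0, "polygon": box(0, 0, 0.2, 1)},
        {"year": 2007, "low_db": 55.0, "high_db": 60.0, "polygon": box(0.2, 0, 0.5, 1)},
        {"year": 2007, "low_db": 60.0, "high_db": 65.0, "polygon": box(0.5, 0, 1, 1)},
    ]
    nm = NoiseMap(daypart="night", band_width=5.0, bands=pd.DataFrame(bands))
    geom = unit_square_geometry()
    post = noise_to_areas(nm, geom)
    mean_ref = 0.2 * 52.5 + 0.3 * 57.5 + 0.5 * 62.5
    var_ref = (0.2 * (25 / 12 + 52.5**2) + 0.3 * (25 / 12 + 57.5**2)
               + 0.5 * (25 / 12 + 62.5**2)) - mean_ref**2
    assert post.table["mean"].iloc[0] == pytest.approx(mean_ref, abs=1e-9)
    assert post.table["sd"].iloc[0] == pytest.approx(math.sqrt(var_ref), abs=1e-9)


def unit_square_geometry():
    """A one-polygon 'city' covering the unit square (bypasses the generator)."""
    from envineq.geometry import DOMAIN_KM2, CityGeometry

    poly = box(0, 0, 1, 1)
    return CityGeometry(area_ids=[1], polygons=[poly],
                        centroids=np.array([[0.5, 0.5]]),
                        neighbors={1: set()}, area_km2=np.array([DOMAIN_KM2]))


def test_band_splitting_invariance():
    """Splitting a band polygon into sub-polygons leaves the aggregate unchanged."""
    import pandas as pd

    whole = make_two_band_map(0.4)
    split = NoiseMap(daypart="daytime", band_width=5.0, bands=pd.DataFrame([
        {"year": 2007, "low_db": 55.0, "high_db": 60.0, "polygon": box(0, 0, 0.4, 0.5)},
        {"year": 2007, "low_db": 55.0, "high_db": 60.0, "polygon": box(0, 0.5, 0.4, 1)},
        {"year": 2007, "low_db": 60.0, "high_db": 65.0, "polygon": box(0.4, 0, 1, 1)},
    ]))
    geom = unit_square_geometry()
    a = noise_to_areas(whole, geom).table
    b = noise_to_areas(split, geom).table
    assert a["mean"].iloc[0] == pytest.approx(b["mean"].iloc[0], abs=1e-12)
    assert a["sd"].iloc[0] == pytest.approx(b["sd"].iloc[0], abs=1e-12)


def test_partial_coverage_raises_with_area_list():
    import pandas as pd

    nm = NoiseMap(daypart="daytime", band_width=5.0, bands=pd.DataFrame([
        {"year": 2007, "low_db": 55.0, "high_db": 60.0, "polygon": box(0, 0, 0.3, 0.3)},
    ]))
    geom = unit_square_geometry()
    with pytest.raises(PartialCoverageError) as exc:
        noise_to_areas(nm, geom)
    assert exc.value.offending_areas == [1]


def test_draw_moments_match_stored_mixture():
    nm = make_two_band_map(0.3)
    geom = unit_square_geometry()
    post = noise_to_areas(nm, geom)
    rng = np.random.default_rng(0)
    draws = post.sample(40_000, rng)
    assert draws.mean() == pytest.approx(post.table["mean"].iloc[0], abs=0.05)
    assert draws.std() == pytest.approx(post.table["sd"].iloc[0], abs=0.05)
    lo = post.table["mean"].iloc[0]
    assert 55.0 <= draws.min() and draws.max() < 65.0 and 55 < lo < 65
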