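"""Change-of-support exposure prediction with quantified uncertainty.

Pollutants are observed at a handful of point monitoring stations while the
health outcomes live on areal units.  This module predicts each hazard at
the neighborhood centroids with a full predictive law, so downstream fits
can propagate exposure uncertainty instead of plugging in a point surface:

* point stations -> exact Gaussian-process regression per year with a
  Matern(nu = 3/2) covariance, hyperparameters by penalized maximum
  marginal likelihood, and a planar trend estimated by GLS (universal
  kriging);
* noise isoline bands -> area-weighted band-midpoint aggregation, with the
  within-band uncertainty of a uniform distribution over each band.

The per-cell predictive laws are bundled into ``ExposurePosterior`` objects
that expose a common sampling interface, and ``assemble_hazard_draws`` turns
a set of them into M complete exposure tables (draw 0 is the plug-in,
posterior-mean table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import optimize

from ._rng import substream
from .errors import (
    AlignmentError,
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    PartialCoverageError,
)
from .geometry import CityGeometry
from .synthetic import NoiseMap, StationSeries

__all__ = [
    "GPConfig",
    "PollutantGP",
    "ExposurePosterior",
    "fit_pollutant_gp",
    "predict_centroid_exposure",
    "noise_to_areas",
    "assemble_hazard_draws",
]

_JITTER = 1e-10


@dataclass(frozen=True)
class GPConfig:
    """Hyperparameter bounds and penalties for the per-year GP fits.

    The weak log-normal penalty on the range keeps the marginal-likelihood
    surface well behaved when only a handful of stations inform it.
    """

    range_bounds: tuple = (0.02, 3.0)
    sd_bounds: tuple = (1e-3, 1e3)
    nugget_bounds: tuple = (1e-4, 1e3)  # nugget standard deviation
    range_penalty_median: float = 0.3
    range_penalty_log_sd: float = 1.5
    mean: object = "linear"  # "linear" (GLS planar trend), "profile" (GLS constant), or a fixed float
    n_restarts: int = 2
    fixed_params: Optional[tuple] = None  # (range, sd, nugget_sd) to skip optimisation


def _matern32(d: np.ndarray, rho: float) -> np.ndarray:
    s = math.sqrt(3.0) * d / rho
    return (1.0 + s) * np.exp(-s)


def _pairwise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)


class _YearGP:
    """Exact GP regression for a single year of station data.

    The mean is either a fixed constant or a trend estimated by GLS:
    ``"profile"`` profiles a constant, ``"linear"`` a planar trend in the
    coordinates (universal kriging) — the robust default for urban fields
    with city-scale gradients.  Trend-estimation uncertainty enters the
    predictive covariance through the usual universal-kriging correction.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: GPConfig):
        self.X = X
        self.y = y
        self.cfg = cfg
        self.params = None  # (range, sd, nugget_sd)
        self.beta = None    # GLS trend coefficients

    def _trend(self, pts: np.ndarray) -> Optional[np.ndarray]:
        if self.cfg.mean == "profile":
            return np.ones((len(pts), 1))
        if self.cfg.mean == "linear":
            return np.column_stack([np.ones(len(pts)), pts])
        return None  # fixed numeric mean

    def _nll(self, log_params: np.ndarray) -> float:
        rho, sd, nug = np.exp(log_params)
        k = sd**2 * _matern32(self._d, rho)
        k[np.diag_indices_from(k)] += nug**2 + _JITTER
        try:
            chol = np.linalg.cholesky(k)
        except np.linalg.LinAlgError:
            return 1e10
        n = len(self.y)
        f = self._trend(self.X)
        if f is not None:
            fw = np.linalg.solve(chol, f)
            yw = np.linalg.solve(chol, self.y)
            beta, *_ = np.linalg.lstsq(fw, yw, rcond=None)
            resid = self.y - f @ beta
        else:
            resid = self.y - float(self.cfg.mean)
        r = np.linalg.solve(chol, resid)
        nll = 0.5 * r @ r + np.log(np.diag(chol)).sum() + 0.5 * n * math.log(2 * math.pi)
        # weak log-normal penalty on the range
        z = (math.log(rho) - math.log(self.cfg.range_penalty_median)) / self.cfg.range_penalty_log_sd
        nll += 0.5 * z * z
        return float(nll)

    def fit(self) -> "_YearGP":
        self._d = _pairwise(self.X, self.X)
        cfg = self.cfg
        if cfg.fixed_params is not None:
            self.params = tuple(float(v) for v in cfg.fixed_params)
        else:
            bounds = [
                (math.log(cfg.range_bounds[0]), math.log(cfg.range_bounds[1])),
                (math.log(cfg.sd_bounds[0]), math.log(cfg.sd_bounds[1])),
                (math.log(cfg.nugget_bounds[0]), math.log(cfg.nugget_bounds[1])),
            ]
            sd0 = max(self.y.std(), 1e-3)
            starts = [np.array([math.log(cfg.range_penalty_median), math.log(sd0), math.log(sd0 / 3)])]
            rng = np.random.default_rng(0)
            for _ in range(cfg.n_restarts):
                starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))
            best = None
            for s0 in starts:
                res = optimize.minimize(self._nll, s0, method="L-BFGS-B", bounds=bounds)
                if best is None or res.fun < best.fun:
                    best = res
            if best is None or not np.isfinite(best.fun):
                raise FitFailureError("GP marginal-likelihood optimisation failed")
            self.params = tuple(np.exp(best.x))
        rho, sd, nug = self.params
        k = sd**2 * _matern32(self._d, rho)
        k[np.diag_indices_from(k)] += nug**2 + _JITTER
        self._chol = np.linalg.cholesky(k)
        f = self._trend(self.X)
        if f is not None:
            fw = np.linalg.solve(self._chol, f)
            yw = np.linalg.solve(self._chol, self.y)
            gram = fw.T @ fw
            self.beta = np.linalg.solve(gram, fw.T @ yw)
            self._trend_gram_inv = np.linalg.inv(gram)
            resid = self.y - f @ self.beta
        else:
            self.beta = None
            self._trend_gram_inv = None
            resid = self.y - float(self.cfg.mean)
        self._alpha = np.linalg.solve(self._chol.T, np.linalg.solve(self._chol, resid))
        return self

    @property
    def mean(self) -> float:
        """Constant part of the fitted trend (for reporting)."""
        return float(self.beta[0]) if self.beta is not None else float(self.cfg.mean)

    def predict(self, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Joint predictive mean and covariance of the noise-free surface."""
        rho, sd, _ = self.params
        kx = sd**2 * _matern32(_pairwise(Xnew, self.X), rho)
        v = np.linalg.solve(self._chol, kx.T)
        kxx = sd**2 * _matern32(_pairwise(Xnew, Xnew), rho)
        cov = kxx - v.T @ v
        fnew = self._trend(Xnew)
        if fnew is not None:
            f = self._trend(self.X)
            fw = np.linalg.solve(self._chol, f)
            mean = fnew @ self.beta + kx @ self._alpha
            rmat = fnew.T - fw.T @ v  # trend-estimation correction
            cov = cov + rmat.T @ self._trend_gram_inv @ rmat
        else:
            mean = float(self.cfg.mean) + kx @ self._alpha
        return mean, cov


@dataclass
class PollutantGP:
    """Per-year fitted GP surfaces for one hazard."""

    hazard: str
    years: list
    models: dict  # year -> _YearGP
    config: GPConfig

    def hyperparameters(self) -> pd.DataFrame:
        rows = [
            {"year": y, "range": m.params[0], "sd": m.params[1], "nugget_sd": m.params[2],
             "mean": m.mean}
            for y, m in self.models.items()
        ]
        return pd.DataFrame(rows)


def fit_pollutant_gp(
    stations: StationSeries,
    geom: CityGeometry,
    gp_config: Optional[GPConfig] = None,
) -> PollutantGP:
    """Fit one exact GP per year to a hazard's station records."""
    cfg = gp_config or GPConfig()
    models = {}
    years = sorted(stations.records["year"].unique())
    for year in years:
        sub = stations.records[stations.records["year"] == year]
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        if np.unique(pts, axis=0).shape[0] < 3:
            raise InsufficientDataError(
                f"year {year}: need >= 3 stations at distinct locations"
            )
        models[year] = _YearGP(pts, sub["value"].to_numpy(dtype=float), cfg).fit()
    return PollutantGP(hazard=stations.hazard, years=years, models=models, config=cfg)


@dataclass
class ExposurePosterior:
    """Predictive law of one hazard at every (area, year).

    ``table`` holds the closed-form predictive mean and sd; ``sample`` draws
    joint predictive realisations (correct cross-area covariance for GP
    provenance, independent band mixtures for isoline provenance).
    """

    hazard: str
    table: pd.DataFrame  # columns: area_id, year, mean, sd
    provenance: str      # "gp" or "isoline"
    draws: Optional[np.ndarray] = None  # (M, n_rows) optional cached draws
    _sampler: Optional[Callable] = field(default=None, repr=False)

    def index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.table["area_id"], self.table["year"]], names=["area_id", "year"]
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, n_rows) joint predictive draws aligned with ``table`` rows."""
        if self._sampler is not None:
            return self._sampler(n, rng)
        sd = self.table["sd"].to_numpy()
        mean = self.table["mean"].to_numpy()
        return mean + rng.standard_normal((n, len(mean))) * sd


def predict_centroid_exposure(
    model: PollutantGP,
    geom: CityGeometry,
    n_draws: int = 0,
    seed: int = 0,
) -> ExposurePosterior:
    """Joint predictive law of the hazard at all area centroids, per year."""
    if n_draws < 0:
        raise InvalidArgumentError("n_draws must be >= 0")
    per_year = {}
    rows = []
    for year in model.years:
        mean, cov = model.models[year].predict(geom.centroids)
        var = np.clip(np.diag(cov), 0.0, None)
        per_year[year] = (mean, cov)
        for k, aid in enumerate(geom.area_ids):
            rows.append({"area_id": aid, "year": year, "mean": mean[k], "sd": math.sqrt(var[k])})
    table = pd.DataFrame(rows)

    chols = {}
    for year, (mean, cov) in per_year.items():
        c = cov + _JITTER * np.eye(cov.shape[0])
        # symmetric eigendecomposition tolerates the near-singular covariances
        w, v = np.linalg.eigh(c)
        chols[year] = (mean, v * np.sqrt(np.clip(w, 0.0, None)))

    def sampler(n, rng):
        out = np.empty((n, len(table)))
        pos = 0
        for year in model.years:
            mean, root = chols[year]
            k = len(mean)
            z = rng.standard_normal((n, root.shape[1]))
            out[:, pos:pos + k] = mean + z @ root.T
            pos += k
        return out

    post = ExposurePosterior(
        hazard=model.hazard, table=table, provenance="gp", _sampler=sampler
    )
    if n_draws:
        post.draws = post.sample(n_draws, substream(seed, f"gp-draws-{model.hazard}"))
    return post


def noise_to_areas(
    noisemap: NoiseMap,
    geom: CityGeometry,
    coverage_tol: float = 0.99,
) -> ExposurePosterior:
    """Aggregate isoline bands to areal support.

    Per area and year the predictive law is the area-weighted mixture of
    uniform distributions on the overlapping bands: the mean is the weighted
    band midpoint and the sd the full mixture standard deviation
    (band_width / sqrt(12) when a single band covers the area).
    """
    years = sorted(noisemap.bands["year"].unique())
    rows = []
    mixtures = []  # per row: (weights, lows, highs)
    offending = []
    for year in years:
        sub = noisemap.bands[noisemap.bands["year"] == year]
        for k, aid in enumerate(geom.area_ids):
            poly = geom.polygons[k]
            weights, los, his = [], [], []
            for _, band in sub.iterrows():
                a = poly.intersection(band["polygon"]).area
                if a > 0:
                    weights.append(a)
                    los.append(band["low_db"])
                    his.append(band["high_db"])
            covered = sum(weights) / poly.area if poly.area > 0 else 0.0
            if covered < coverage_tol:
                offending.append((aid, year, covered))
                continue
            w = np.asarray(weights) / sum(weights)
            lo = np.asarray(los)
            hi = np.asarray(his)
            mid = 0.5 * (lo + hi)
            mean = float(w @ mid)
            var = float(w @ ((hi - lo) ** 2 / 12.0 + mid**2) - mean**2)
            rows.append({"area_id": aid, "year": year, "mean": mean, "sd": math.sqrt(max(var, 0.0))})
            mixtures.append((w, lo, hi))
    if offending:
        raise PartialCoverageError(
            f"noise bands cover less than {coverage_tol:.0%} of some areas: "
            + ", ".join(f"area {a} year {y} ({c:.1%})" for a, y, c in offending[:10]),
            offending_areas=[a for a, _, _ in offending],
        )
    table = pd.DataFrame(rows)

    def sampler(n, rng):
        out = np.empty((n, len(mixtures)))
        for j, (w, lo, hi) in enumerate(mixtures):
            bi = rng.choice(len(w), size=n, p=w)
            out[:, j] = rng.uniform(lo[bi], hi[bi])
        return out

    return ExposurePosterior(
        hazard=f"noise_{noisemap.daypart}", table=table, provenance="isoline", _sampler=sampler
    )


def assemble_hazard_draws(
    posteriors: list,
    M: int,
    seed: int = 0,
) -> list:
    """M complete exposure tables; draw 0 is the plug-in (posterior-mean) table.

    Hazards are sampled independently, each from its own seed stream derived
    from the hazard name, so the draw sequence of one hazard never depends
    on which other hazards are present or their order.
    """
    if M < 1:
        raise InvalidArgumentError("M must be >= 1")
    ref = posteriors[0].index()
    for p in posteriors[1:]:
        if not ref.equals(p.index()):
            raise AlignmentError(
                f"posterior for {p.hazard!r} is not aligned with {posteriors[0].hazard!r}"
            )
    base = posteriors[0].table[["area_id", "year"]].copy()
    plug_in = base.copy()
    for p in posteriors:
        plug_in[p.hazard] = p.table["mean"].to_numpy()
    tables = [plug_in]
    if M > 1:
        all_draws = {}
        for p in posteriors:
            rng = substream(seed, f"hazard-draws-{p.hazard}")
            all_draws[p.hazard] = p.sample(M - 1, rng)
        for m in range(M - 1):
            t = base.copy()
            for p in posteriors:
                t[p.hazard] = all_draws[p.hazard][m]
            tables.append(t)
    return tables
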