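"""Exposure-differential and susceptibility-differential assessments.

Exposure differential: do predicted hazard levels differ across income
quintiles?  Tested nonparametrically (Kruskal–Wallis H on the posterior-mean
predictions, quintiles rebuilt within each year) and descriptively through a
penalized-spline smooth of predicted exposure on income.

Susceptibility differential: build a binary polluted-neighborhood indicator
(hazard predictions in the top two yearly quintiles), then fit the summary
ecological regression whose quintile-by-indicator interactions measure
whether equal exposure harms deprived neighborhoods more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .design import ModelSpec, build_design
from .errors import AlignmentError, InvalidArgumentError
from .fit import HealthFit, fit_health_model, pool_over_draws, relative_risks
from .quintiles import quintile_labels, yearly_quintiles

__all__ = [
    "ExposureGradientResult",
    "SusceptibilityReport",
    "yearly_quintiles",
    "kruskal_wallis_h",
    "smooth_gradient",
    "polluted_indicator",
    "fit_susceptibility",
]


# --------------------------------------------------------------------------
# Kruskal–Wallis


def kruskal_wallis_h(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with a chi-square p-value.

    Returns ``(H, df, p)``.  When every observation is identical the test is
    degenerate and the documented convention ``H = 0, p = 1`` applies.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InvalidArgumentError("Kruskal–Wallis needs at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise InvalidArgumentError("every group must be nonempty")
    df = len(labels) - 1
    if np.all(values == values[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p)


# --------------------------------------------------------------------------
# penalized-spline smooth


@dataclass
class SmoothFit:
    """Penalized cubic B-spline regression of exposure on income."""

    grid: np.ndarray
    fitted: np.ndarray
    edf: float
    statistic: float
    p_value: float
    gcv_lambda: float
    bulk_trend: float = 0.0  # rank correlation of the fit over the data bulk

    @property
    def slope_sign(self) -> int:
        """Sign of the overall trend across the bulk of the income range.

        Measured as the rank correlation between the fitted curve and income
        over the central 10-90% of the observed income distribution, which
        keeps the sparse, wiggly tails of the smooth from dominating.
        """
        return int(np.sign(self.bulk_trend))


def _bspline_basis(x: np.ndarray, knots_interior: int, degree: int = 3):
    lo, hi = x.min(), x.max()
    span = max(hi - lo, 1e-12)
    inner = np.quantile(x, np.linspace(0, 1, knots_interior + 2)[1:-1])
    knots = np.concatenate(
        [np.full(degree + 1, lo - 1e-9 * span), np.sort(inner), np.full(degree + 1, hi + 1e-9 * span)]
    )
    return BSpline.design_matrix(x, knots, degree).toarray(), knots


def smooth_gradient(
    exposure_mean,
    income,
    knots: int = 12,
    grid_size: int = 100,
) -> SmoothFit:
    """Penalized cubic B-spline smooth of predicted exposure on income.

    The smoothing parameter minimises generalized cross-validation over a
    log-spaced grid; a first-order difference penalty shrinks toward a
    constant, so the effective degrees of freedom approach 1 under the null.
    Significance of the smooth is a Wald-type chi-square comparing the
    penalized fit against the constant model on ``edf - 1`` degrees of
    freedom (bounded below by 1).
    """
    y = np.asarray(exposure_mean, dtype=float)
    x = np.asarray(income, dtype=float)
    if len(y) != len(x):
        raise AlignmentError("exposure and income must have equal length")
    if len(y) < 20:
        raise InvalidArgumentError("smooth_gradient needs at least 20 observations")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("income is constant; the smooth is undefined")

    b, knots_vec = _bspline_basis(x, knots)
    n, k = b.shape
    d = np.diff(np.eye(k), axis=0)  # first-order differences: null space = constants
    btb = b.T @ b
    bty = b.T @ y
    pen = d.T @ d

    best = None
    for lam in np.logspace(-4, 10, 57) * np.trace(btb) / k:
        m = btb + lam * pen
        try:
            coef = np.linalg.solve(m, bty)
        except np.linalg.LinAlgError:
            continue
        fitted = b @ coef
        rss = float(np.sum((y - fitted) ** 2))
        edf = float(np.trace(np.linalg.solve(m, btb)))
        denom = max(n - edf, 1e-9)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, fitted, rss, edf)
    _, lam, coef, fitted, rss, edf = best

    rss0 = float(np.sum((y - y.mean()) ** 2))
    sigma2 = rss / max(n - edf, 1.0)
    statistic = max(rss0 - rss, 0.0) / max(sigma2, 1e-300)
    df_test = max(edf - 1.0, 1.0)
    p = float(stats.chi2.sf(statistic, df_test))

    grid = np.linspace(x.min(), x.max(), grid_size)
    bg = BSpline.design_matrix(np.clip(grid, x.min(), x.max()), knots_vec, 3).toarray()
    q10, q90 = np.quantile(x, [0.1, 0.9])
    bulk = (x >= q10) & (x <= q90)
    trend = stats.spearmanr(x[bulk], fitted[bulk]).statistic if bulk.sum() >= 3 else 0.0
    return SmoothFit(
        grid=grid,
        fitted=bg @ coef,
        edf=edf,
        statistic=float(statistic),
        p_value=p,
        gcv_lambda=float(lam),
        bulk_trend=float(0.0 if np.isnan(trend) else trend),
    )


# --------------------------------------------------------------------------
# exposure-differential report


@dataclass
class ExposureGradientResult:
    """Per-hazard quintile summaries, Kruskal–Wallis test and smooth fit."""

    hazard: str
    quintile_summary: pd.DataFrame  # quintile -> mean, sd, median
    h_statistic: float
    df: int
    p_value: float
    smooth: SmoothFit

    def to_row(self) -> dict:
        row = {"hazard": self.hazard, "kw_h": self.h_statistic, "kw_df": self.df,
               "kw_p": self.p_value, "gam_edf": self.smooth.edf,
               "gam_p": self.smooth.p_value}
        for q in range(1, 6):
            sub = self.quintile_summary.loc[q]
            row[f"q{q}_mean"] = sub["mean"]
            row[f"q{q}_sd"] = sub["sd"]
            row[f"q{q}_median"] = sub["median"]
        return row


def assess_exposure_gradient(
    exposure: pd.DataFrame,
    income: pd.Series,
    hazard: str,
) -> ExposureGradientResult:
    """Full exposure-differential assessment for one hazard.

    ``exposure`` holds posterior-mean predictions (columns area_id, year,
    <hazard>); ``income`` is indexed by (area_id, year).  Quintiles are
    rebuilt within each year.
    """
    idx = pd.MultiIndex.from_arrays(
        [exposure["area_id"], exposure["year"]], names=["area_id", "year"]
    )
    inc = income.reindex(idx)
    if inc.isna().any():
        raise AlignmentError("income does not cover every exposure (area, year)")
    quint = yearly_quintiles(inc).labels.to_numpy()
    vals = exposure[hazard].to_numpy(dtype=float)
    h, df, p = kruskal_wallis_h(vals, quint)
    summary = (
        pd.DataFrame({"quintile": quint, "value": vals})
        .groupby("quintile")["value"]
        .agg(["mean", "std", "median"])
        .rename(columns={"std": "sd"})
    )
    smooth = smooth_gradient(vals, inc.to_numpy())
    return ExposureGradientResult(
        hazard=hazard, quintile_summary=summary,
        h_statistic=h, df=df, p_value=p, smooth=smooth,
    )


# --------------------------------------------------------------------------
# polluted-neighborhood indicator


def polluted_indicator(
    exposures: pd.DataFrame,
    hazards: list,
    quintile_rule: str = "all",
) -> pd.DataFrame:
    """Binary polluted flag per (area, year).

    A neighborhood-year is flagged when its predicted hazard levels sit in
    the fourth or fifth yearly quintile — for every listed hazard under rule
    ``"all"`` (the literal conjunction), or for at least one under ``"any"``.
    Rank-based quintiles make the indicator invariant to monotone transforms
    of the hazard levels.
    """
    if quintile_rule not in ("all", "any"):
        raise InvalidArgumentError("quintile_rule must be 'all' or 'any'")
    missing = sorted(set(hazards) - set(exposures.columns))
    if missing:
        raise AlignmentError(f"exposure table is missing hazards: {missing}")
    exposures = exposures.reset_index(drop=True)
    out = exposures[["area_id", "year"]].copy()
    flags = np.ones(len(out), dtype=bool) if quintile_rule == "all" else np.zeros(len(out), dtype=bool)
    for hz in hazards:
        top = np.zeros(len(out), dtype=bool)
        for year, sub in exposures.groupby("year"):
            lab = quintile_labels(sub[hz].to_numpy(dtype=float))
            top[sub.index.to_numpy()] = lab >= 4
        flags = flags & top if quintile_rule == "all" else flags | top
    out["polluted"] = flags.astype(int)
    return out


# --------------------------------------------------------------------------
# susceptibility differential


@dataclass
class SusceptibilityReport:
    """Relative-risk table of the summary (polluted-indicator) regression."""

    rows: pd.DataFrame
    sex: str
    quintile_rule: str
    m_draws: int
    seed: int
    fit: HealthFit

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


_INESTIMABLE_SD = 10.0  # a posterior this wide means the design carries no signal


def _report_rows(fit: HealthFit) -> pd.DataFrame:
    """Order the RR table: indicator main effect, quintile mains, interactions."""
    rr = relative_risks(fit).set_index("term")
    sd = pd.Series(fit.sd, index=fit.columns)
    ordered = []

    def ref_row(term):
        return {"term": term, "RR": 1.0, "lo95": np.nan, "hi95": np.nan,
                "lo90": np.nan, "hi90": np.nan, "flag95": False, "flag90": False,
                "formatted": "1 [reference]", "estimable": True}

    def add(term):
        if term not in rr.index:
            return
        row = rr.loc[term].to_dict()
        row["term"] = term
        row["estimable"] = bool(sd[term] < _INESTIMABLE_SD)
        if not row["estimable"]:
            row.update(flag95=False, flag90=False, formatted="inestimable")
        ordered.append(row)

    ordered.append(ref_row("non_polluted"))
    add("polluted")
    ordered.append(ref_row("income_q1"))
    for q in range(2, 6):
        add(f"income_q{q}")
    for q in range(2, 6):
        add(f"polluted:q{q}")
    for term in rr.index:
        if term not in {r["term"] for r in ordered}:
            add(term)
    return pd.DataFrame(ordered)


def fit_susceptibility(
    panel: pd.DataFrame,
    indicator: pd.DataFrame,
    spec: ModelSpec,
    geom=None,
    seed: int = 0,
    indicator_draws: Optional[list] = None,
    pool_weights: str = "evidence",
) -> SusceptibilityReport:
    """Fit the summary regression and report Table-style relative risks.

    ``indicator`` is the (area_id, year, polluted) table built from the
    plug-in exposure predictions.  When ``indicator_draws`` is given (one
    indicator table per exposure draw) the model is refitted per draw and
    the posteriors pooled.
    """
    if spec.form != "polluted":
        raise InvalidArgumentError("fit_susceptibility requires a 'polluted'-form spec")
    design = build_design(panel, indicator, spec, geom=geom)
    fit = fit_health_model(design, spec, seed=seed)
    m_draws = 1
    if indicator_draws:
        fits = [fit]
        for k, ind in enumerate(indicator_draws):
            d = build_design(panel, ind, spec, geom=geom)
            fits.append(fit_health_model(d, spec, seed=seed + 1 + k))
        fit = pool_over_draws(fits, weights=pool_weights, seed=seed)
        m_draws = len(fits)
    rows = _report_rows(fit)
    return SusceptibilityReport(
        rows=rows,
        sex=spec.sex,
        quintile_rule="all",
        m_draws=m_draws,
        seed=seed,
        fit=fit,
    )
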