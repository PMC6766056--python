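"""Yearly income quintiles — the single shared definition.

Both the design-matrix builder and the inequality assessments call into this
module, so the simulator, the fitter and the reporting code agree exactly on
which areas fall in which quintile.

The assignment is rank based and computed separately within each year.  When
n is not divisible by 5 the lower-income groups take the extra members
("larger lower groups first"): n = 73 gives group sizes 15, 15, 15, 14, 14.
Ties are broken by stable rank order, which makes the labels invariant to any
strictly monotone transformation of the values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import QuintileError

__all__ = ["quintile_labels", "yearly_quintiles", "QuintileAssignment"]


def quintile_labels(values: np.ndarray) -> np.ndarray:
    """Quintile label (1..5, increasing with value) for one year's values."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 5:
        raise QuintileError(f"need at least 5 observations per year, got {n}")
    if np.unique(values).size < 5:
        raise QuintileError("fewer than 5 distinct values: quintiles undefined")
    order = np.argsort(values, kind="stable")
    base, extra = divmod(n, 5)
    sizes = [base + 1 if q < extra else base for q in range(5)]
    labels = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = q
        start += size
    return labels


class QuintileAssignment:
    """Per (area, year) quintile labels plus the yearly cut points."""

    def __init__(self, labels: pd.Series, cutpoints: dict):
        self.labels = labels  # index (area_id, year) -> 1..5
        self.cutpoints = cutpoints  # year -> array of 4 interior cut values

    def for_year(self, year) -> pd.Series:
        return self.labels.xs(year, level="year")


def yearly_quintiles(income: pd.Series) -> QuintileAssignment:
    """Assign income quintiles separately within each year.

    Parameters
    ----------
    income
        Series indexed by a MultiIndex with levels ``area_id`` and ``year``.
    """
    if not isinstance(income.index, pd.MultiIndex):
        raise QuintileError("income must be indexed by (area_id, year)")
    labels = pd.Series(0, index=income.index, dtype=int, name="quintile")
    cutpoints = {}
    for year, grp in income.groupby(level="year"):
        lab = quintile_labels(grp.to_numpy())
        labels.loc[grp.index] = lab
        vals = np.sort(grp.to_numpy())
        # interior cut = midpoint between the last member of q and the first of q+1
        sizes = np.bincount(lab, minlength=6)[1:]
        idx = np.cumsum(sizes)[:-1]
        cutpoints[year] = 0.5 * (vals[idx - 1] + vals[idx])
    return QuintileAssignment(labels, cutpoints)
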