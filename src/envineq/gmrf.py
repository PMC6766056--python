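"""Gaussian Markov random field building blocks.

The spatially structured effect uses a Matern-type GMRF built on the area
adjacency graph in the spirit of the SPDE construction: with graph Laplacian
L and positive weight matrix D (relative polygon areas, standing in for the
finite-element volumes),

    Q0 = (kappa**2 D + L)^T D^{-1} (kappa**2 D + L),   kappa = sqrt(8) / range

is the precision of a smoothness-one Markov field whose correlation decays
over ``range`` in map units.  Q0 is rescaled so the average marginal variance
equals sd**2, making ``sd`` interpretable on the data scale.

The temporal trend uses the standard first-order random-walk structure
matrix, rank T-1, with an explicit sum-to-zero constraint.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .errors import GraphError, InvalidArgumentError
from .geometry import CityGeometry

__all__ = ["matern_gmrf_precision", "rw1_precision", "sample_gmrf"]

_JITTER = 1e-10


def matern_gmrf_precision(geom: CityGeometry, range_r: float, sd: float) -> sparse.csc_matrix:
    """Sparse precision of the Matern-type spatial effect over areas.

    Scaled so that mean(diag(Q**-1)) == sd**2.
    """
    if range_r <= 0:
        raise InvalidArgumentError("range_r must be positive")
    if sd <= 0:
        raise InvalidArgumentError("sd must be positive")
    n = geom.n_areas
    adj = geom.adjacency_matrix()
    deg = adj.sum(axis=1)
    if np.any(deg == 0) and n > 1:
        raise GraphError("adjacency graph is disconnected")
    lap = np.diag(deg) - adj
    w = geom.area_km2 / geom.area_km2.mean()
    kappa2 = 8.0 / range_r**2
    k = kappa2 * np.diag(w) + lap
    q0 = k.T @ np.diag(1.0 / w) @ k
    q0[np.diag_indices_from(q0)] += _JITTER
    v0 = np.diag(np.linalg.inv(q0))
    # c**2 = 1/mean(v0) makes the average marginal variance 1 before sd-scaling
    q = q0 * (v0.mean() / sd**2)
    q[np.diag_indices_from(q)] += _JITTER
    return sparse.csc_matrix(q)


def rw1_precision(T: int) -> tuple[np.ndarray, np.ndarray]:
    """First-order random-walk structure matrix and its sum-to-zero constraint.

    Returns
    -------
    R
        (T, T) tridiagonal structure matrix; rank T-1; constant vectors lie
        in its null space.
    constraint
        Length-T vector c with the identifiability constraint c @ x = 0.
    """
    if T < 2:
        raise InvalidArgumentError("RW1 needs at least 2 time points")
    r = np.zeros((T, T))
    idx = np.arange(T)
    r[idx, idx] = 2.0
    r[0, 0] = r[-1, -1] = 1.0
    r[idx[:-1], idx[:-1] + 1] = -1.0
    r[idx[:-1] + 1, idx[:-1]] = -1.0
    return r, np.ones(T)


def sample_gmrf(Q, rng: np.random.Generator, center: bool = True) -> np.ndarray:
    """One draw from N(0, Q**-1) via Cholesky of the (dense) precision."""
    qd = Q.toarray() if sparse.issparse(Q) else np.asarray(Q, dtype=float)
    chol = np.linalg.cholesky(qd)
    z = rng.standard_normal(qd.shape[0])
    x = np.linalg.solve(chol.T, z)
    if center:
        x = x - x.mean()
    return x


def rw1_sample(T: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Centered RW1 path with innovation standard deviation ``sd``."""
    if T < 2:
        raise InvalidArgumentError("RW1 needs at least 2 time points")
    path = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, sd, size=T - 1))])
    return path - path.mean()
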