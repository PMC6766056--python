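"""Inference for the spatio-temporal Poisson ecological regression.

The latent field stacks the fixed effects with the structured random effects
(Matern spatial field S, iid area heterogeneity alpha, RW1 yearly trend T)
and, separately, the iid area-year interaction eta which has one entry per
observation.  Conditional on the hyperparameters the model is a latent
Gaussian Poisson regression:

    O_it ~ Poisson(exp(x_it' beta + S_i + alpha_i + T_t + eta_it + log Pop_it))

``laplace`` inference finds the joint posterior mode of the latent field by
Newton iterations, optimises the hyperparameters on the Laplace-approximate
marginal likelihood (with PC priors on the precisions and a log-normal prior
on the spatial range), and reports the Gaussian approximation at the mode —
an empirical-Bayes Laplace scheme.  Because eta contributes a diagonal block
with one entry per observation, each Newton step is taken through the Schur
complement on the non-eta block, which keeps the per-iteration cost at
O(n * m^2) for m structured latents rather than O((m + n)^3).

``mcmc`` runs Metropolis-within-Gibbs with a one-step-Newton
(weighted-least-squares) Gaussian proposal for the structured block,
componentwise updates for eta, and log-scale random walks for the
hyperparameters, with acceptance rates adapted during burn-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from ._rng import substream
from .design import DesignBundle, ModelSpec
from .errors import ConvergenceError, FitFailureError, PoolingError
from .gmrf import matern_gmrf_precision, rw1_precision
from .priors import pc_prior_logdensity

__all__ = ["HealthFit", "fit_health_model", "pool_over_draws", "fit_over_exposure_draws", "relative_risks", "format_rr"]

_LINPRED_CAP = 30.0  # guards exp() overflow during early Newton steps
_GRAD_TOL_SCALE = 1e-9


# --------------------------------------------------------------------------
# containers


@dataclass
class HealthFit:
    """Posterior summaries for one fitted model.

    Fixed effects are stored as a mean vector plus covariance (laplace) or as
    draws (mcmc / pooled fits); quantiles fall back to the Gaussian form when
    no draws are available.
    """

    columns: list
    mean: np.ndarray
    cov: Optional[np.ndarray]
    draws: Optional[np.ndarray]
    scalers: dict
    hyper: dict
    random_effects: dict
    method: str
    provenance: str
    converged: bool
    diagnostics: dict
    log_marginal: float
    spec: ModelSpec
    components: list = dataclass_field(default_factory=list)  # mixture parts when pooled

    @property
    def sd(self) -> np.ndarray:
        if self.draws is not None:
            return self.draws.std(axis=0, ddof=1)
        return np.sqrt(np.diag(self.cov))

    def fixed_quantile(self, q: float) -> np.ndarray:
        if self.draws is not None:
            return np.quantile(self.draws, q, axis=0)
        return self.mean + norm.ppf(q) * self.sd

    def coefficient(self, name: str) -> float:
        return float(self.mean[self.columns.index(name)])

    def coefficient_interval(self, name: str, level: float = 0.95) -> tuple:
        j = self.columns.index(name)
        a = (1.0 - level) / 2.0
        return (float(self.fixed_quantile(a)[j]), float(self.fixed_quantile(1 - a)[j]))

    def sample_fixed(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.draws is not None:
            idx = rng.integers(0, self.draws.shape[0], size=n)
            return self.draws[idx]
        chol = np.linalg.cholesky(self.cov + 1e-12 * np.eye(len(self.mean)))
        return self.mean + rng.standard_normal((n, len(self.mean))) @ chol.T

    def summary(self) -> pd.DataFrame:
        lo, hi = self.fixed_quantile(0.025), self.fixed_quantile(0.975)
        return pd.DataFrame(
            {
                "term": self.columns,
                "mean": self.mean,
                "sd": self.sd,
                "median": self.fixed_quantile(0.5),
                "q2.5": lo,
                "q97.5": hi,
            }
        )

    def to_dict(self) -> dict:
        out = {
            "columns": list(self.columns),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "hyper": self.hyper,
            "method": self.method,
            "provenance": self.provenance,
            "converged": bool(self.converged),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if np.isscalar(v) or isinstance(v, (bool, str))},
            "log_marginal": float(self.log_marginal),
        }
        return out


# --------------------------------------------------------------------------
# latent structure


class _Structure:
    """Design expansion and prior precision for the structured latent block."""

    def __init__(self, design: DesignBundle, spec: ModelSpec):
        self.design = design
        self.spec = spec
        n = design.n_obs
        p = design.n_fixed
        nA = len(design.area_ids)
        nT = len(design.years)
        re = spec.random_effects
        blocks = [("fixed", p)]
        parts = [design.X]
        if re.spatial:
            if design.geom is None:
                raise FitFailureError("spatial effect requested but design has no geometry")
            z = np.zeros((n, nA)); z[np.arange(n), design.area_index] = 1.0
            blocks.append(("spatial", nA)); parts.append(z)
        if re.iid_area:
            z = np.zeros((n, nA)); z[np.arange(n), design.area_index] = 1.0
            blocks.append(("iid_area", nA)); parts.append(z)
        if re.rw1:
            z = np.zeros((n, nT)); z[np.arange(n), design.year_index] = 1.0
            blocks.append(("rw1", nT)); parts.append(z)
        self.blocks = blocks
        self.A = np.concatenate(parts, axis=1)
        self.m = self.A.shape[1]
        self.has_eta = re.interaction
        self.hyper_names = []
        if re.spatial:
            self.hyper_names += ["log_range", "log_tau_spatial"]
        if re.iid_area:
            self.hyper_names.append("log_tau_iid_area")
        if re.rw1:
            self.hyper_names.append("log_tau_rw1")
        if self.has_eta:
            self.hyper_names.append("log_tau_interaction")
        r, _ = rw1_precision(nT) if re.rw1 else (None, None)
        self._rw1_struct = None
        if re.rw1:
            self._rw1_struct = r + np.ones((nT, nT)) / nT  # soft sum-to-zero
        self._nA, self._nT = nA, nT

    def hyper_dict(self, theta: np.ndarray) -> dict:
        return dict(zip(self.hyper_names, theta))

    def prior_precision(self, theta: np.ndarray) -> np.ndarray:
        """Dense prior precision of the structured block for hypers theta."""
        h = self.hyper_dict(theta)
        q = np.zeros((self.m, self.m))
        pos = 0
        for name, size in self.blocks:
            sl = slice(pos, pos + size)
            if name == "fixed":
                q[sl, sl] = np.eye(size) * self.spec.fixed_effect_precision
            elif name == "spatial":
                rng_val = math.exp(h["log_range"])
                tau = math.exp(h["log_tau_spatial"])
                qm = matern_gmrf_precision(self.design.geom, rng_val, 1.0).toarray()
                q[sl, sl] = tau * (qm + np.ones((size, size)) / size)
            elif name == "iid_area":
                q[sl, sl] = np.eye(size) * math.exp(h["log_tau_iid_area"])
            elif name == "rw1":
                q[sl, sl] = math.exp(h["log_tau_rw1"]) * self._rw1_struct
            pos += size
        return q

    def tau_eta(self, theta: np.ndarray) -> float:
        return math.exp(self.hyper_dict(theta)["log_tau_interaction"]) if self.has_eta else 0.0

    def hyper_logprior(self, theta: np.ndarray) -> float:
        h = self.hyper_dict(theta)
        lp = 0.0
        for comp in ("spatial", "iid_area", "rw1", "interaction"):
            key = f"log_tau_{comp}"
            if key in h:
                tau = math.exp(h[key])
                # + log tau is the Jacobian of the log-precision parameterisation
                lp += pc_prior_logdensity(tau, self.spec.pc_priors[comp]) + h[key]
        if "log_range" in h:
            rng_val = math.exp(h["log_range"])
            lp += self.spec.range_prior.logpdf(rng_val) + h["log_range"]
        return lp

    def block_slice(self, name: str) -> slice:
        pos = 0
        for bname, size in self.blocks:
            if bname == name:
                return slice(pos, pos + size)
            pos += size
        raise KeyError(name)

    def initial_theta(self) -> np.ndarray:
        init = []
        for name in self.hyper_names:
            if name == "log_range":
                init.append(math.log(self.spec.range_prior.median))
            else:
                init.append(math.log(1.0 / 0.1**2))  # start every sd at 0.1
        return np.array(init)


# --------------------------------------------------------------------------
# Laplace machinery


def _newton_mode(struct, q_prior, tau_eta, z0, eta0, y, offset, max_iter=60):
    """Posterior mode of (z, eta) by damped Newton with a Schur-complement step."""
    a = struct.A
    n = a.shape[0]
    z = z0.copy()
    eta = eta0.copy() if struct.has_eta else None
    tol = _GRAD_TOL_SCALE * (1.0 + y.sum())

    def objective(zv, ev):
        ell = a @ zv + offset + (ev if ev is not None else 0.0)
        ell = np.clip(ell, -_LINPRED_CAP, _LINPRED_CAP)
        mu = np.exp(ell)
        f = float(y @ ell - mu.sum()) - 0.5 * zv @ (q_prior @ zv)
        if ev is not None:
            f -= 0.5 * tau_eta * ev @ ev
        return f, ell, mu

    f, ell, mu = objective(z, eta)
    info = {"converged": False, "iterations": 0, "grad_norm": np.inf}
    for it in range(1, max_iter + 1):
        resid = y - mu
        gz = a.T @ resid - q_prior @ z
        if struct.has_eta:
            ge = resid - tau_eta * eta
            d = mu + tau_eta
            wd = mu / d
            aw = a * (mu * (1.0 - wd))[:, None]
            s = a.T @ aw + q_prior
            rhs = gz - a.T @ (wd * ge)
        else:
            ge = None
            s = a.T @ (a * mu[:, None]) + q_prior
            rhs = gz
        try:
            cf = cho_factor(s, lower=True)
        except np.linalg.LinAlgError as exc:
            raise FitFailureError("Newton Hessian not positive definite") from exc
        dz = cho_solve(cf, rhs)
        de = (ge - mu * (a @ dz)) / d if struct.has_eta else None
        step = 1.0
        for _ in range(30):
            z_try = z + step * dz
            e_try = eta + step * de if struct.has_eta else None
            f_try, ell_try, mu_try = objective(z_try, e_try)
            if f_try >= f - 1e-12:
                break
            step *= 0.5
        z, eta, f, ell, mu = z_try, e_try, f_try, ell_try, mu_try
        gnorm = max(np.abs(gz).max(), np.abs(ge).max() if ge is not None else 0.0)
        info.update(iterations=it, grad_norm=float(gnorm))
        if gnorm < tol:
            info["converged"] = True
            break
    return z, eta, mu, f, cf, s, info


def _laplace_marginal(struct, theta, y, offset, warm):
    """Laplace-approximate log marginal likelihood at hyperparameters theta."""
    q_prior = struct.prior_precision(theta)
    tau_eta = struct.tau_eta(theta)
    n = struct.A.shape[0]
    z0 = warm.get("z", np.zeros(struct.m))
    eta0 = warm.get("eta", np.zeros(n))
    z, eta, mu, f_mode, cf, s, info = _newton_mode(struct, q_prior, tau_eta, z0, eta0, y, offset)
    warm["z"], warm["eta"] = z, (eta if eta is not None else np.zeros(n))

    sign, logdet_q = np.linalg.slogdet(q_prior)
    if sign <= 0:
        raise FitFailureError("prior precision not positive definite")
    logdet_s = 2.0 * np.log(np.diag(cf[0])).sum()
    lml = f_mode - special.gammaln(y + 1.0).sum() + 0.5 * logdet_q - 0.5 * logdet_s
    if struct.has_eta:
        d = mu + tau_eta
        lml += 0.5 * n * math.log(tau_eta) - 0.5 * np.log(d).sum()
    lml += struct.hyper_logprior(theta)
    return lml, (z, eta, mu, cf, s, info, q_prior, tau_eta)


def _posterior_from_mode(struct, state):
    z, eta, mu, cf, s, info, q_prior, tau_eta = state
    m = struct.m
    cov_z = cho_solve(cf, np.eye(m))
    p = struct.design.n_fixed
    re_summ = {}
    for name, _size in struct.blocks[1:]:
        sl = struct.block_slice(name)
        re_summ[name] = {
            "mean": z[sl].copy(),
            "sd": np.sqrt(np.clip(np.diag(cov_z)[sl], 0.0, None)),
        }
    if struct.has_eta:
        d = mu + tau_eta
        acov = struct.A @ cov_z
        quad = np.einsum("ij,ij->i", acov, struct.A)
        re_summ["interaction"] = {
            "mean": eta.copy(),
            "sd": np.sqrt(np.clip(1.0 / d + (mu / d) ** 2 * quad, 0.0, None)),
        }
    return z[:p].copy(), cov_z[:p, :p].copy(), re_summ


def _hyper_uncertainty_correction(struct, theta_hat, y, offset, warm, mean_f, h=0.15):
    """First-order (Kass–Steffey) fixed-effect covariance inflation.

    Empirical-Bayes conditioning on the modal hyperparameters understates
    posterior spread.  The correction adds J C J', where J is the
    sensitivity of the fixed-effect posterior mean to the log
    hyperparameters and C the inverse curvature of the Laplace marginal at
    its mode, both by central finite differences.  Flat directions of the
    marginal (weakly identified hyperparameters) are capped rather than
    allowed to blow the variance up.
    """
    k = len(theta_hat)
    p = len(mean_f)

    def marginal(theta):
        lml, _ = _laplace_marginal(struct, theta, y, offset, dict(warm))
        return lml

    def mode_mean(theta):
        _, st = _laplace_marginal(struct, theta, y, offset, dict(warm))
        return st[0][:p]

    jac = np.zeros((p, k))
    grad_pairs = {}
    for i in range(k):
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[i] += h
        tm[i] -= h
        mp, mm = mode_mean(tp), mode_mean(tm)
        jac[:, i] = (mp - mm) / (2 * h)
        grad_pairs[i] = (marginal(tp), marginal(tm))
    f0 = marginal(theta_hat)
    hess = np.zeros((k, k))
    for i in range(k):
        fp, fm = grad_pairs[i]
        hess[i, i] = -(fp - 2 * f0 + fm) / h**2
    for i in range(k):
        for j in range(i + 1, k):
            tpp = theta_hat.copy(); tpp[[i, j]] += h
            tmm = theta_hat.copy(); tmm[[i, j]] -= h
            tpm = theta_hat.copy(); tpm[i] += h; tpm[j] -= h
            tmp = theta_hat.copy(); tmp[i] -= h; tmp[j] += h
            hess[i, j] = hess[j, i] = -(
                marginal(tpp) - marginal(tpm) - marginal(tmp) + marginal(tmm)
            ) / (4 * h**2)
    w, v = np.linalg.eigh(hess)
    # cap hyperparameter variances: sd at most 2 on the log scale
    w = np.clip(w, 0.25, None)
    cov_theta = (v / w) @ v.T
    return jac @ cov_theta @ jac.T


def _fit_laplace(design: DesignBundle, spec: ModelSpec, seed: int) -> HealthFit:
    struct = _Structure(design, spec)
    y, offset = design.y, design.offset
    warm: dict = {}

    if struct.hyper_names:
        theta0 = struct.initial_theta()

        def neg(theta):
            try:
                lml, _ = _laplace_marginal(struct, theta, y, offset, warm)
            except FitFailureError:
                return 1e12
            return -lml if np.isfinite(lml) else 1e12

        res = optimize.minimize(
            neg,
            theta0,
            method="Nelder-Mead",
            options={
                "maxfev": spec.max_opt_evals,
                "xatol": 0.02,
                "fatol": 0.02,
                "adaptive": True,
            },
        )
        theta_hat = res.x
        n_evals = int(res.nfev)
    else:
        theta_hat = np.array([])
        n_evals = 0

    lml, state = _laplace_marginal(struct, theta_hat, y, offset, warm)
    if not np.isfinite(lml):
        raise FitFailureError("non-finite Laplace marginal at the optimum")
    mean_f, cov_f, re_summ = _posterior_from_mode(struct, state)
    info = state[5]
    if struct.hyper_names:
        cov_f = cov_f + _hyper_uncertainty_correction(
            struct, theta_hat, y, offset, warm, mean_f
        )

    h = struct.hyper_dict(theta_hat)
    hyper = {}
    for comp in ("spatial", "iid_area", "rw1", "interaction"):
        key = f"log_tau_{comp}"
        if key in h:
            hyper[f"sd_{comp}"] = math.exp(-0.5 * h[key])
    if "log_range" in h:
        hyper["range_spatial"] = math.exp(h["log_range"])

    converged = bool(info["converged"])
    if spec.strict and not converged:
        raise ConvergenceError(f"Newton gradient norm {info['grad_norm']:.3g} above tolerance")
    return HealthFit(
        columns=list(design.columns),
        mean=mean_f,
        cov=cov_f,
        draws=None,
        scalers=dict(design.scalers),
        hyper=hyper,
        random_effects=re_summ,
        method="laplace",
        provenance="plug-in",
        converged=converged,
        diagnostics={
            "newton_iterations": info["iterations"],
            "grad_norm": info["grad_norm"],
            "hyper_evals": n_evals,
        },
        log_marginal=float(lml),
        spec=spec,
    )


# --------------------------------------------------------------------------
# MCMC


def _mcmc_chain(struct, spec, y, offset, theta, z, eta, rng, n_iter, adapt_until):
    """One Metropolis-within-Gibbs chain; returns fixed-effect and hyper draws.

    The structured block uses the one-step-Newton (weighted-least-squares)
    proposal: from the current state, take one Newton step of the
    conditional log posterior and propose from the Gaussian centred there
    with the local Hessian as precision.  The proposal re-centres at every
    iteration, so it tracks the hyperparameters as they move; the asymmetry
    is corrected exactly in the acceptance ratio.
    """
    a = struct.A
    n = a.shape[0]
    p = struct.design.n_fixed
    q_prior = struct.prior_precision(theta)
    tau_eta = struct.tau_eta(theta)
    sign, logdet_q = np.linalg.slogdet(q_prior)

    def loglik_terms(zv, ev):
        ell = np.clip(a @ zv + offset + (ev if ev is not None else 0.0),
                      -_LINPRED_CAP, _LINPRED_CAP)
        return ell, np.exp(ell)

    def newton_proposal_params(zv, q):
        """Mean and Cholesky precision of the one-step-Newton Gaussian."""
        ell_v, mu_v = loglik_terms(zv, eta)
        h = a.T @ (a * mu_v[:, None]) + q
        grad = a.T @ (y - mu_v) - q @ zv
        cf = cho_factor(h, lower=True)
        mean = zv + cho_solve(cf, grad)
        return mean, cf

    def log_q_density(x, mean, cf):
        d = x - mean
        # cho_factor leaves garbage in the strict upper triangle
        return -0.5 * d @ cho_solve(cf, d) + np.log(np.diag(cf[0])).sum()

    ell, mu = loglik_terms(z, eta)
    lp_z = float(y @ ell - mu.sum()) - 0.5 * z @ (q_prior @ z)

    s_eta = 1.0
    s_theta = np.full(len(struct.hyper_names), 0.3)
    acc_z = acc_t = 0
    fixed_draws, hyper_draws = [], []
    n_hyper = len(struct.hyper_names)

    for it in range(n_iter):
        # --- structured block, one-step-Newton Gaussian proposal
        mean_f, cf_f = newton_proposal_params(z, q_prior)
        lower_f = np.tril(cf_f[0])
        xi = rng.standard_normal(struct.m)
        prop = mean_f + np.linalg.solve(lower_f.T, xi)
        ell_p, mu_p = loglik_terms(prop, eta)
        lp_p = float(y @ ell_p - mu_p.sum()) - 0.5 * prop @ (q_prior @ prop)
        mean_r, cf_r = newton_proposal_params(prop, q_prior)
        lq_fwd = log_q_density(prop, mean_f, cf_f)
        lq_rev = log_q_density(z, mean_r, cf_r)
        if math.log(rng.uniform()) < (lp_p - lp_z) + (lq_rev - lq_fwd):
            z, ell, mu, lp_z = prop, ell_p, mu_p, lp_p
            acc_z += 1
        # --- eta, componentwise (a posteriori independent given z)
        if struct.has_eta:
            step = s_eta / np.sqrt(mu + tau_eta)
            eta_p = eta + step * rng.standard_normal(n)
            ell_base = np.clip(a @ z + offset, -_LINPRED_CAP, _LINPRED_CAP)
            cur = y * (ell_base + eta) - np.exp(np.clip(ell_base + eta, -_LINPRED_CAP, _LINPRED_CAP)) \
                - 0.5 * tau_eta * eta**2
            new = y * (ell_base + eta_p) - np.exp(np.clip(ell_base + eta_p, -_LINPRED_CAP, _LINPRED_CAP)) \
                - 0.5 * tau_eta * eta_p**2
            take = np.log(rng.uniform(size=n)) < new - cur
            eta = np.where(take, eta_p, eta)
            ell, mu = loglik_terms(z, eta)
            lp_z = float(y @ ell - mu.sum()) - 0.5 * z @ (q_prior @ z)
        # --- hyperparameters, one-at-a-time log random walks
        for k in range(n_hyper):
            prop_t = theta.copy()
            prop_t[k] += s_theta[k] * rng.standard_normal()
            q_p = struct.prior_precision(prop_t)
            tau_p = struct.tau_eta(prop_t)
            sign_p, logdet_p = np.linalg.slogdet(q_p)
            if sign_p <= 0:
                continue
            num = -0.5 * z @ (q_p @ z) + 0.5 * logdet_p + struct.hyper_logprior(prop_t)
            den = -0.5 * z @ (q_prior @ z) + 0.5 * logdet_q + struct.hyper_logprior(theta)
            if struct.has_eta:
                num += -0.5 * tau_p * eta @ eta + 0.5 * n * math.log(tau_p)
                den += -0.5 * tau_eta * eta @ eta + 0.5 * n * math.log(tau_eta)
            if math.log(rng.uniform()) < num - den:
                theta, q_prior, tau_eta, logdet_q = prop_t, q_p, tau_p, logdet_p
                lp_z = float(y @ ell - mu.sum()) - 0.5 * z @ (q_prior @ z)
                acc_t += 1
        # --- adapt the hyperparameter steps toward the 20-40% window
        if it < adapt_until and it > 0 and it % 50 == 0 and n_hyper:
            rate_t = acc_t / (50.0 * n_hyper)
            s_theta *= math.exp(0.5 * (rate_t - 0.3))
            acc_t = 0
        if it >= adapt_until:
            fixed_draws.append(z[:p].copy())
            hyper_draws.append(theta.copy())
    return np.array(fixed_draws), np.array(hyper_draws)


def _fit_mcmc(design: DesignBundle, spec: ModelSpec, seed: int) -> HealthFit:
    import arviz as az

    lap = _fit_laplace(design, spec, seed)
    struct = _Structure(design, spec)
    theta0 = np.array(
        [math.log(lap.hyper["range_spatial"]) if n == "log_range"
         else -2.0 * math.log(lap.hyper[f"sd_{n.removeprefix('log_tau_')}"])
         for n in struct.hyper_names]
    )
    warm: dict = {}
    _, state = _laplace_marginal(struct, theta0, design.y, design.offset, warm)
    z0, eta0 = state[0], (state[1] if struct.has_eta else None)

    chains_f, chains_h = [], []
    for c in range(2):
        rng = substream(seed, f"mcmc-chain-{c}")
        f_draws, h_draws = _mcmc_chain(
            struct, spec, design.y, design.offset,
            theta0.copy(), z0.copy(),
            eta0.copy() if eta0 is not None else None,
            rng,
            n_iter=spec.mcmc_iterations, adapt_until=spec.mcmc_burn,
        )
        chains_f.append(f_draws)
        chains_h.append(h_draws)
    stacked = np.stack(chains_f)  # (chain, draw, p)
    ds = az.convert_to_dataset(stacked)
    rhat = float(az.rhat(ds)["x"].max())
    ess = float(az.ess(ds)["x"].min())
    draws = stacked.reshape(-1, stacked.shape[-1])
    converged = rhat < 1.1
    if spec.strict and not converged:
        raise ConvergenceError(f"MCMC R-hat {rhat:.3f} exceeds 1.1")

    hyper = dict(lap.hyper)
    if chains_h[0].size:
        h_mean = np.concatenate(chains_h).mean(axis=0)
        for name, val in zip(struct.hyper_names, h_mean):
            if name == "log_range":
                hyper["range_spatial"] = math.exp(val)
            else:
                hyper[f"sd_{name.removeprefix('log_tau_')}"] = math.exp(-0.5 * val)

    return HealthFit(
        columns=list(design.columns),
        mean=draws.mean(axis=0),
        cov=np.cov(draws.T) if draws.shape[0] > 2 else lap.cov,
        draws=draws,
        scalers=dict(design.scalers),
        hyper=hyper,
        random_effects=lap.random_effects,
        method="mcmc",
        provenance="plug-in",
        converged=converged,
        diagnostics={"rhat_max": rhat, "ess_min": ess},
        log_marginal=lap.log_marginal,
        spec=spec,
    )


def fit_health_model(design: DesignBundle, spec: Optional[ModelSpec] = None, seed: int = 0) -> HealthFit:
    """Fit the ecological Poisson regression described by ``spec``.

    Parameters
    ----------
    design
        Output of :func:`envineq.design.build_design`.
    spec
        Model specification; defaults to the one stored on the design.
    seed
        Master seed for any stochastic step (MCMC); the Laplace path is
        deterministic.
    """
    spec = spec or design.spec
    if spec.method == "laplace":
        return _fit_laplace(design, spec, seed)
    return _fit_mcmc(design, spec, seed)


# --------------------------------------------------------------------------
# pooling over exposure draws


def pool_over_draws(
    fits: list,
    weights: str = "equal",
    n_samples: int = 4000,
    seed: int = 0,
) -> HealthFit:
    """Pool posteriors fitted on different exposure draws.

    ``weights="equal"`` forms the multiple-imputation-style equal-weight
    mixture.  ``weights="evidence"`` weights each component by its Laplace
    marginal likelihood, which importance-reweights the exposure draws by how
    well they explain the observed deaths — the tractable approximation to
    fitting exposure and health jointly.
    """
    if len(fits) < 2:
        raise PoolingError("pooling needs at least 2 fits")
    cols = fits[0].columns
    form = fits[0].spec.form
    for f in fits[1:]:
        if f.columns != cols or f.spec.form != form:
            raise PoolingError("cannot pool fits with different specifications")
    if weights == "equal":
        w = np.full(len(fits), 1.0 / len(fits))
    elif weights == "evidence":
        lml = np.array([f.log_marginal for f in fits])
        w = np.exp(lml - lml.max())
        w /= w.sum()
    else:
        raise PoolingError(f"unknown weighting scheme {weights!r}")

    rng = substream(seed, "pool-over-draws")
    counts = rng.multinomial(n_samples, w)
    draws = np.concatenate(
        [f.sample_fixed(c, rng) for f, c in zip(fits, counts) if c > 0], axis=0
    )
    mean = w @ np.array([f.mean for f in fits])
    # analytic mixture covariance (law of total variance) when available
    mix_cov = None
    if all(f.cov is not None for f in fits):
        mix_cov = np.zeros((len(mean), len(mean)))
        for wi, f in zip(w, fits):
            d = f.mean - mean
            mix_cov += wi * (f.cov + np.outer(d, d))
    return HealthFit(
        columns=list(cols),
        mean=mean,
        cov=mix_cov if mix_cov is not None else np.cov(draws.T),
        draws=draws,
        scalers=dict(fits[0].scalers),
        hyper=dict(fits[0].hyper),
        random_effects={},
        method=fits[0].method,
        provenance="M-draw pooled",
        converged=all(f.converged for f in fits),
        diagnostics={"n_components": len(fits), "weighting": weights},
        log_marginal=float(np.average([f.log_marginal for f in fits], weights=w)),
        spec=fits[0].spec,
        components=[(float(wi), f.mean, f.cov) for wi, f in zip(w, fits)],
    )


# --------------------------------------------------------------------------
# exposure-uncertainty propagation


def fit_over_exposure_draws(
    panel,
    exposure_tables: list,
    spec: ModelSpec,
    geom=None,
    seed: int = 0,
    scheme: str = "sir",
    sir_iterations: int = 3,
    n_pool: Optional[int] = None,
) -> tuple:
    """Fit the health model under exposure uncertainty.

    ``exposure_tables`` is the output of ``assemble_hazard_draws``: table 0
    is the plug-in (posterior-mean) exposure, tables 1.. are joint draws
    from the exposure predictive law and serve as the proposal bank; the
    pooled posterior mixes ``n_pool`` fits (default: one per draw).
    Returns ``(plug_in_fit, pooled_fit)``.

    Schemes
    -------
    ``equal``
        Multiple-imputation-style: one fit per draw, equal-weight mixture.
        Propagates exposure uncertainty into the posterior spread but cannot
        undo attenuation of the point estimate (each draw adds classical
        measurement error).
    ``evidence``
        Components weighted by their Laplace marginal likelihood.
    ``sir``
        Sampling-importance-resampling approximation to the joint
        exposure-health posterior: exposure draws are independent across
        years, so year blocks are reweighted by the Poisson likelihood of
        that year's deaths at the current coefficient estimate, resampled
        into complete tables, refitted and pooled; iterated a few times.
        Feeding the death counts back into the exposure distribution is
        what counteracts the attenuation that the plug-in estimate suffers
        when stations are few and noisy.
    """
    from .design import build_design  # local import avoids a cycle at module load

    if scheme not in ("equal", "evidence", "sir"):
        raise PoolingError(f"unknown propagation scheme {scheme!r}")
    d_plug = build_design(panel, exposure_tables[0], spec, geom=geom)
    plug_fit = fit_health_model(d_plug, spec, seed=seed)
    scal = d_plug.scalers
    if len(exposure_tables) < 2:
        return plug_fit, plug_fit

    if scheme in ("equal", "evidence"):
        fits = [plug_fit]
        for k, t in enumerate(exposure_tables[1:]):
            d = build_design(panel, t, spec, geom=geom, fixed_scalers=scal)
            fits.append(fit_health_model(d, spec, seed=seed + 1 + k))
        return plug_fit, pool_over_draws(fits, weights=scheme, seed=seed)

    rng = substream(seed, "sir-propagation")
    hazard_cols = [c for c in exposure_tables[0].columns if c not in ("area_id", "year")]
    years = sorted(exposure_tables[0]["year"].unique())
    n_bank = len(exposure_tables) - 1
    n_out = min(n_pool or n_bank, n_bank)
    beta = plug_fit.mean.copy()
    pooled = plug_fit
    for _ in range(max(sir_iterations, 1)):
        # per-draw, per-year Poisson log likelihood at the current coefficients
        lw = np.zeros((n_bank, len(years)))
        for m, t in enumerate(exposure_tables[1:]):
            d = build_design(panel, t, spec, geom=geom, fixed_scalers=scal)
            ell = np.clip(d.X @ beta + d.offset, -_LINPRED_CAP, _LINPRED_CAP)
            ll = d.y * ell - np.exp(ell)
            for j in range(len(years)):
                lw[m, j] = ll[d.year_index == j].sum()
        fits = []
        for k in range(n_out):
            stitched = exposure_tables[0][["area_id", "year"]].copy()
            vals = np.zeros((len(stitched), len(hazard_cols)))
            for j, yr in enumerate(years):
                w = np.exp(lw[:, j] - lw[:, j].max())
                w /= w.sum()
                pick = rng.choice(n_bank, p=w)
                mask = (stitched["year"] == yr).to_numpy()
                vals[mask] = exposure_tables[1 + pick].loc[mask, hazard_cols].to_numpy()
            stitched[hazard_cols] = vals
            d = build_design(panel, stitched, spec, geom=geom, fixed_scalers=scal)
            fits.append(fit_health_model(d, spec, seed=seed + 101 + k))
        pooled = pool_over_draws(fits, weights="equal", seed=seed)
        beta = pooled.mean.copy()
    pooled.provenance = "M-draw pooled"
    pooled.diagnostics["propagation"] = "sir"
    return plug_fit, pooled


# --------------------------------------------------------------------------
# relative risks


def format_rr(rr: float, lo: float, hi: float) -> str:
    """Three-decimal point-and-interval string, e.g. ``0.794 (0.632–1.002)``."""
    return f"{rr:.3f} ({lo:.3f}–{hi:.3f})"


def relative_risks(fit: HealthFit) -> pd.DataFrame:
    """Relative risks per term with 90/95% credibility intervals and flags.

    Coefficients of standardized continuous covariates are rescaled back to
    the original units (RR per one unit of the raw covariate); dummy and
    indicator terms are reported as-is.  A flag is set when the corresponding
    interval excludes 1.
    """
    rows = []
    for j, term in enumerate(fit.columns):
        if term == "intercept":
            continue
        base = term.split(":")[0]
        scale = fit.scalers.get(base, (0.0, 1.0))[1]
        # log-RRs clipped so pathologically wide posteriors stay representable
        def _exp(q):
            return math.exp(min(max(q / scale, -500.0), 500.0))

        rr = _exp(fit.fixed_quantile(0.5)[j])
        l95 = _exp(fit.fixed_quantile(0.025)[j])
        h95 = _exp(fit.fixed_quantile(0.975)[j])
        l90 = _exp(fit.fixed_quantile(0.05)[j])
        h90 = _exp(fit.fixed_quantile(0.95)[j])
        rows.append(
            {
                "term": term,
                "RR": rr,
                "lo95": l95,
                "hi95": h95,
                "lo90": l90,
                "hi90": h90,
                "flag95": bool(l95 > 1.0 or h95 < 1.0),
                "flag90": bool(l90 > 1.0 or h90 < 1.0),
                "formatted": format_rr(rr, l95, h95),
            }
        )
    return pd.DataFrame(rows)
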