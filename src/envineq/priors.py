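"""Hyperparameter priors: penalised-complexity (PC) and log-normal.

The PC prior for the standard deviation sigma of a Gaussian random effect
shrinks toward the base model sigma = 0.  It is parameterised through a tail
statement P(sigma > u) = alpha_tail, which implies an exponential prior with
rate lambda = -ln(alpha_tail) / u on sigma.  Expressed on the precision
tau = sigma**-2 the density is

    pi(tau) = (lambda / 2) * tau**(-3/2) * exp(-lambda * tau**(-1/2))

which is the form used throughout the fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidArgumentError

__all__ = ["PCPrior", "LogNormalPrior", "pc_prior_logdensity"]


@dataclass(frozen=True)
class PCPrior:
    """P(sd > u) = alpha_tail prior on the sd of a Gaussian effect."""

    u: float = 1.0
    alpha_tail: float = 0.01

    def __post_init__(self):
        if not self.u > 0:
            raise InvalidArgumentError("PCPrior.u must be positive")
        if not 0 < self.alpha_tail < 1:
            raise InvalidArgumentError("PCPrior.alpha_tail must lie in (0, 1)")

    @property
    def rate(self) -> float:
        """Implied exponential rate on the sd scale."""
        return -math.log(self.alpha_tail) / self.u


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal prior used for the spatial range hyperparameter."""

    median: float = 0.3
    log_sd: float = 1.0

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        z = (math.log(x) - math.log(self.median)) / self.log_sd
        return -0.5 * z * z - math.log(x * self.log_sd) - 0.5 * math.log(2 * math.pi)


def pc_prior_logdensity(tau: float, prior: PCPrior) -> float:
    """Log density of the PC prior evaluated on the precision scale.

    Parameters
    ----------
    tau
        Precision (inverse variance) of the Gaussian effect; must be > 0.
    prior
        Tail specification ``P(sd > u) = alpha_tail``.
    """
    if tau <= 0:
        raise InvalidArgumentError("pc_prior_logdensity requires tau > 0")
    lam = prior.rate
    return math.log(lam / 2.0) - 1.5 * math.log(tau) - lam / math.sqrt(tau)
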