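"""Empirical-Bayes gamma-Poisson shrinkage (MGPS-style EBGM).

Model: for each drug-event cell the observed count ``a`` is Poisson with
mean ``lambda * E``, where ``E = (a+c)(a+b)/N`` is the count expected under
row/column independence and ``lambda`` is the cell's true relative
reporting ratio.  ``lambda`` has a two-component gamma mixture prior

    lambda ~ w * Gamma(alpha1, beta1) + (1-w) * Gamma(alpha2, beta2)

(shape/rate), so the marginal of ``a`` given ``E`` is a mixture of two
negative binomials.  The five prior parameters are fitted by maximum
likelihood over all cells; the posterior of ``lambda`` given ``(a, E)`` is
again a two-gamma mixture, and

    EBGM  = exp(E[ln lambda | a, E])        (posterior geometric mean)
    EB05  = 5th posterior percentile, EB95 = 95th.

Shrinkage pulls sparse cells toward 1, which is what distinguishes these
values from the unshrunk relative reporting ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.special import digamma, gammaln
from scipy.stats import gamma as gamma_dist

from .contingency import ContingencyTable
from .disproportionality import EstimateCI


@dataclass(frozen=True)
class GpsPrior:
    """Two-gamma mixture prior (shape alpha_k, rate beta_k, weight w)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0 < self.w < 1:
            raise ValueError("mixture weight must be in (0, 1)")


#: DuMouchel's classic starting point for the FDA database
DEFAULT_START = GpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, w=1 / 3)


class GpsFitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best-so-far fit."""

    def __init__(self, message: str, best_prior: GpsPrior):
        super().__init__(message)
        self.best_prior = best_prior


def _nb_logpmf(a, e, alpha: float, beta: float):
    """log NegBin(a; alpha, p=beta/(beta+e)) — the gamma-Poisson marginal."""
    logp = np.log(beta) - np.log(beta + e)
    log1mp = np.log(e) - np.log(beta + e)
    return (
        gammaln(alpha + a) - gammaln(alpha) - gammaln(a + 1)
        + alpha * logp + a * log1mp
    )


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    w = 1 / (1 + math.exp(-theta[4]))
    l1 = _nb_logpmf(a, e, a1, b1) + math.log(w)
    l2 = _nb_logpmf(a, e, a2, b2) + math.log(1 - w)
    return float(np.logaddexp(l1, l2).sum())


# fixed multi-start grid: (alpha1, beta1, alpha2, beta2, w)
_STARTS = (
    (0.2, 0.1, 2.0, 4.0, 1 / 3),
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.5, 5.0, 5.0, 0.2),
    (0.1, 0.1, 10.0, 10.0, 0.5),
    (2.0, 2.0, 0.2, 0.2, 0.5),
    (1.0, 0.5, 20.0, 20.0, 0.1),
    (0.05, 0.05, 1.0, 1.0, 0.3),
    (3.0, 1.0, 50.0, 50.0, 0.05),
)


def fit_gps_prior(
    tables: Sequence[ContingencyTable] | None = None,
    counts: Iterable[float] | None = None,
    expected: Iterable[float] | None = None,
    min_cells: int = 50,
) -> GpsPrior:
    """Maximum-likelihood fit of the two-gamma prior over all cells.

    Input is either a sequence of contingency tables (cells are their ``a``
    counts and independence expectations) or explicit ``counts``/``expected``
    arrays.  Deterministic: a fixed multi-start grid feeds L-BFGS-B on
    log/logit-transformed parameters and the best converged optimum wins.
    """
    if tables is not None:
        a = np.asarray([t.a for t in tables], dtype=float)
        e = np.asarray([t.expected_a for t in tables], dtype=float)
    else:
        a = np.asarray(list(counts), dtype=float)
        e = np.asarray(list(expected), dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]
    if a.size < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells with positive expectation, got {a.size}"
        )

    def nll(theta):
        return -_mixture_loglik(theta, a, e)

    best = None
    converged = False
    for start in _STARTS:
        theta0 = np.array(
            [math.log(start[0]), math.log(start[1]), math.log(start[2]),
             math.log(start[3]), math.log(start[4] / (1 - start[4]))]
        )
        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B",
            bounds=[(-12, 12)] * 4 + [(-12, 12)],
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    a1, b1, a2, b2 = np.exp(best.x[:4])
    w = 1 / (1 + math.exp(-best.x[4]))
    w = min(max(w, 1e-9), 1 - 1e-9)
    prior = GpsPrior(float(a1), float(b1), float(a2), float(b2), float(w))
    if not converged:
        raise GpsFitError("no optimizer start converged", prior)
    return prior


def _posterior_mixture(a: float, e: float, prior: GpsPrior):
    """Posterior component parameters and weights given (a, E)."""
    la = _nb_logpmf(np.array(a, float), np.array(e, float), prior.alpha1, prior.beta1)
    lb = _nb_logpmf(np.array(a, float), np.array(e, float), prior.alpha2, prior.beta2)
    l1 = float(la) + math.log(prior.w)
    l2 = float(lb) + math.log(1 - prior.w)
    m = max(l1, l2)
    q1 = math.exp(l1 - m) / (math.exp(l1 - m) + math.exp(l2 - m))
    comps = (
        (q1, prior.alpha1 + a, prior.beta1 + e),
        (1 - q1, prior.alpha2 + a, prior.beta2 + e),
    )
    return comps


def _mixture_cdf(x: float, comps) -> float:
    return sum(q * gamma_dist.cdf(x, shape, scale=1 / rate)
               for q, shape, rate in comps)


def _mixture_quantile(p: float, comps, tol: float = 1e-8) -> float:
    # the quantile lies between the smallest and largest component quantile
    lo = min(gamma_dist.ppf(p, shape, scale=1 / rate) for _, shape, rate in comps)
    hi = max(gamma_dist.ppf(p, shape, scale=1 / rate) for _, shape, rate in comps)
    if hi - lo <= tol:
        return 0.5 * (lo + hi)
    f_lo = _mixture_cdf(lo, comps) - p
    f_hi = _mixture_cdf(hi, comps) - p
    # when one component carries (almost) all the posterior weight the CDF
    # already meets p at a bracket edge up to rounding
    if f_lo >= 0:
        return lo
    if f_hi <= 0:
        return hi
    return float(optimize.brentq(
        lambda x: _mixture_cdf(x, comps) - p, lo, hi, xtol=tol
    ))


def posterior_ebgm(
    a: float, e: float, prior: GpsPrior, q_low: float = 0.05, q_high: float = 0.95
) -> EstimateCI:
    """Shrunk EBGM with EB05/EB95 posterior-quantile bounds for one cell.

    EBGM is ``exp`` of the posterior mean of ``ln lambda``, computed in
    closed form from the digamma function under the posterior two-gamma
    mixture; the quantiles come from root-finding on the mixture CDF.
    """
    if e <= 0:
        raise ValueError("expected count must be positive")
    comps = _posterior_mixture(a, e, prior)
    mean_log = sum(
        q * (digamma(shape) - math.log(rate)) for q, shape, rate in comps
    )
    ebgm = math.exp(mean_log)
    return EstimateCI(
        ebgm,
        _mixture_quantile(q_low, comps),
        _mixture_quantile(q_high, comps),
    )


def simulate_cells(
    prior: GpsPrior,
    expected: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw observed counts from the gamma-Poisson mixture at given E values.

    Used for parameter-recovery experiments: each cell draws its component,
    then lambda ~ Gamma, then a ~ Poisson(lambda * E).
    """
    expected = np.asarray(expected, dtype=float)
    comp2 = rng.random(expected.size) >= prior.w
    shape = np.where(comp2, prior.alpha2, prior.alpha1)
    rate = np.where(comp2, prior.beta2, prior.beta1)
    lam = rng.gamma(shape, 1 / rate)
    return rng.poisson(lam * expected)
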