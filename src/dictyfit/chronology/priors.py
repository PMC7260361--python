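"""Priors for the relaxed-clock dating model.

* Soft-bound uniform fossil calibrations: probability mass 1 - 2*tail is
  uniform between the minimum and maximum age constraint; each side carries
  exactly ``tail`` mass (default 2.5%) in an exponential tail matched for
  continuity at the bound.
* Independent-rates clock: branch rates i.i.d. log-normal with mean mu
  (mean-preserving parameterization, log r ~ N(log mu - sigma2/2, sigma2));
  gamma hyperpriors on mu (shape 2, rate 20) and sigma2 (shape 1, rate 10),
  the shape/rate reading of the dating-program convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: default gamma hyperpriors, (shape, rate); means 0.1 per 100 My
MU_HYPERPRIOR = (2.0, 20.0)
SIGMA2_HYPERPRIOR = (1.0, 10.0)


@dataclass(frozen=True)
class Calibration:
    """Soft-bound uniform age constraint on a named node (units of 100 My)."""

    node: str
    t_min: float
    t_max: float
    tail: float = 0.025

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_min < self.t_max:
            raise ValueError("need 0 <= t_min < t_max")
        if not 0.0 < self.tail < 0.5:
            raise ValueError("tail probability must be in (0, 0.5)")

    @property
    def _height(self) -> float:
        core = 1.0 - (2.0 if self.t_min > 0 else 1.0) * self.tail
        return core / (self.t_max - self.t_min)

    @property
    def _scale(self) -> float:
        """Exponential tail scale matched so each tail holds `tail` mass."""
        return self.tail / self._height

    def logpdf(self, t: float) -> float:
        if t <= 0:
            raise ValueError("node age must be > 0")
        h, lam = self._height, self._scale
        if t < self.t_min:
            return math.log(h) - (self.t_min - t) / lam
        if t > self.t_max:
            return math.log(h) - (t - self.t_max) / lam
        return math.log(h)

    def pdf(self, t: float) -> float:
        return math.exp(self.logpdf(t))

    def cdf(self, t) -> np.ndarray:
        """Analytic CDF (vectorized); lower tail truncated at 0 is negligible
        whenever t_min is several tail scales above zero."""
        t = np.asarray(t, dtype=float)
        h, lam = self._height, self._scale
        below = self.tail * np.exp(-(self.t_min - t) / lam)
        core = self.tail + (t - self.t_min) * h
        above = 1.0 - self.tail * np.exp(-(t - self.t_max) / lam)
        out = np.where(t < self.t_min, below,
                       np.where(t <= self.t_max, core, above))
        if self.t_min == 0:
            out = np.where(t < self.t_min, 0.0, (t - self.t_min) * h)
            out = np.where(t > self.t_max,
                           1.0 - self.tail * np.exp(-(t - self.t_max) / lam), out)
        return out

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Inverse-CDF draws (resampling the vanishing sliver below zero)."""
        h, lam = self._height, self._scale
        u = rng.uniform(size=size)
        out = np.empty(size)
        lo = u < self.tail if self.t_min > 0 else np.zeros(size, dtype=bool)
        hi = u > 1.0 - self.tail
        mid = ~lo & ~hi
        with np.errstate(divide="ignore"):
            out[lo] = self.t_min + lam * np.log(u[lo] / self.tail)
        start = self.tail if self.t_min > 0 else 0.0
        out[mid] = self.t_min + (u[mid] - start) / h
        out[hi] = self.t_max - lam * np.log((1.0 - u[hi]) / self.tail)
        bad = out <= 0
        if bad.any():
            out[bad] = self.sample(rng, int(bad.sum()))
        return out


def gamma_logpdf(x: float, shape: float, rate: float) -> float:
    """log density of Gamma(shape, rate) at x."""
    if x <= 0:
        return -math.inf
    return (shape * math.log(rate) - math.lgamma(shape)
            + (shape - 1.0) * math.log(x) - rate * x)


def lognormal_rate_logpdf(rates: np.ndarray, mu: float, sigma2: float) -> float:
    """Sum of mean-preserving log-normal log densities for branch rates."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0) or mu <= 0:
        return -math.inf
    if sigma2 == 0:
        return math.inf if np.allclose(rates, mu) else -math.inf
    m = math.log(mu) - sigma2 / 2.0
    lr = np.log(rates)
    return float(np.sum(-lr - 0.5 * math.log(2.0 * math.pi * sigma2)
                        - (lr - m) ** 2 / (2.0 * sigma2)))


@dataclass
class ClockModel:
    """Independent log-normal branch rates with gamma hyperpriors."""

    mu: float
    sigma2: float
    rates: dict[str, float]
    mu_hyperprior: tuple[float, float] = MU_HYPERPRIOR
    sigma2_hyperprior: tuple[float, float] = SIGMA2_HYPERPRIOR

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mean rate must be > 0")
        if self.sigma2 < 0:
            raise ValueError("rate variance must be >= 0")
        if any(r <= 0 for r in self.rates.values()):
            raise ValueError("all branch rates must be > 0")
        if min(*self.mu_hyperprior, *self.sigma2_hyperprior) <= 0:
            raise ValueError("hyperprior parameters must be > 0")


def clock_prior_logdensity(model: ClockModel) -> float:
    """Gamma hyperprior terms for mu and sigma2 plus the rate log densities."""
    lp = gamma_logpdf(model.mu, *model.mu_hyperprior)
    lp += gamma_logpdf(model.sigma2, *model.sigma2_hyperprior)
    rates = np.array(list(model.rates.values()))
    return lp + lognormal_rate_logpdf(rates, model.mu, model.sigma2)


def expected_branch_lengths(tree, model: ClockModel) -> dict[str, float]:
    """Clock identity: expected length = rate x branch duration."""
    durations = tree.branch_durations()
    missing = set(durations) - set(model.rates)
    if missing:
        raise ValueError(f"missing rates for branches: {sorted(missing)}")
    return {b: model.rates[b] * d for b, d in durations.items()}


def approx_loglik(lengths: dict[str, float], variances: dict[str, float],
                  expected: dict[str, float]) -> float:
    """Independent-Gaussian approximate likelihood of branch-length estimates."""
    total = 0.0
    for b, obs in lengths.items():
        v = variances[b]
        if v <= 0:
            raise ValueError(f"non-positive variance for branch {b!r}")
        e = expected[b]
        total += -((obs - e) ** 2) / (2.0 * v) - 0.5 * math.log(2.0 * math.pi * v)
    return total
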