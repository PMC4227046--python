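"""Moment-matched truncated normals and copula-coupled draws.

Population tables report mean +/- SD together with the observed range. A
truncated normal parameterized naively with the printed mean/SD realizes a
different mean once truncated to the printed range (the truncation pulls the
mean toward the midpoint), so sampled populations would be biased relative to
the table. Here the underlying (mu, sigma) are solved so that the *realized*
truncated moments equal the printed ones.

For some rows the printed SD is larger than the largest SD any truncated
normal supports on the printed interval (the supremum is the uniform limit,
(b-a)/sqrt(12); printed ranges are small-sample ranges and can be narrower
than +/-2 SD). For those rows the mean is matched exactly and the SD saturates
at the feasible maximum; :func:`matched_truncnorm` reports which case applied.

Correlated draws between two matched marginals use a Gaussian copula. The
correlation needed so that a derived quantity (here: the voltage distance to
threshold, delta_V = 1000 * rheobase / G_in) has a prescribed mean is solved
once per group on a fixed internal quadrature sample, independently of the
user's seed, so the calibration is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy import optimize, stats

# Fixed-size standard-normal design used only for calibration integrals.
_CAL_N = 40_000
_CAL_SEED = 987_654_321


@dataclass(frozen=True)
class MatchedTruncNorm:
    """A truncated normal whose realized moments match a table row."""

    mu: float
    sigma: float  # 0 marks a degenerate (point-mass) row
    a: float
    b: float
    sd_feasible: bool  # False when the printed SD saturated at the uniform limit

    @property
    def _frozen(self):
        al = (self.a - self.mu) / self.sigma
        be = (self.b - self.mu) / self.sigma
        return stats.truncnorm(al, be, loc=self.mu, scale=self.sigma)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.full_like(np.asarray(u, dtype=float), self.mu)
        return self._frozen.ppf(u)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))

    def mean_sd(self) -> tuple[float, float]:
        if self.sigma == 0:
            return self.mu, 0.0
        m, v = self._frozen.stats(moments="mv")
        return float(m), float(np.sqrt(v))


def _tn_mean(mu: float, sigma: float, a: float, b: float) -> float:
    al, be = (a - mu) / sigma, (b - mu) / sigma
    return float(stats.truncnorm.stats(al, be, loc=mu, scale=sigma, moments="m"))


def _tn_sd(mu: float, sigma: float, a: float, b: float) -> float:
    al, be = (a - mu) / sigma, (b - mu) / sigma
    return float(np.sqrt(stats.truncnorm.stats(al, be, loc=mu, scale=sigma, moments="v")))


@lru_cache(maxsize=None)
def matched_truncnorm(mean: float, sd: float, a: float, b: float) -> MatchedTruncNorm:
    """Solve (mu, sigma) so TN(mu, sigma; [a, b]) has the given mean and SD.

    The mean equation is solved by 1-D root finding in mu (the truncated mean
    is strictly increasing in mu); the SD equation by root finding in sigma
    along the mean-matched path. The mu bracket must widen like sigma**2: the
    exponential tilt of a normal restricted to a far interval scales as
    (mu - c) / sigma**2.
    """
    if a > b:
        raise ValueError(f"empty truncation interval [{a}, {b}]")
    if not (a <= mean <= b):
        raise ValueError(f"mean {mean} outside [{a}, {b}]")
    if sd == 0 or a == b:
        return MatchedTruncNorm(mean, 0.0, a, b, True)
    w = b - a

    def mu_for(sigma: float) -> float:
        half = max(8 * sigma + 2 * w, 25 * sigma**2 / w)
        c = (a + b) / 2
        return optimize.brentq(
            lambda mu: _tn_mean(mu, sigma, a, b) - mean, c - half, c + half,
            xtol=1e-12 * w,
        )

    def sd_at(sigma: float) -> float:
        return _tn_sd(mu_for(sigma), sigma, a, b)

    sig_hi = 6 * w  # SD is within <1% of the uniform limit here
    if sd_at(sig_hi) <= sd:
        sigma = sig_hi
        feasible = False
    else:
        sigma = optimize.brentq(lambda s: sd_at(s) - sd, w / 200, sig_hi, xtol=1e-12)
        feasible = True
    return MatchedTruncNorm(mu_for(sigma), sigma, a, b, feasible)


def _calibration_normals() -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(_CAL_SEED)
    return rng.standard_normal(_CAL_N), rng.standard_normal(_CAL_N)


def gaussian_copula_pair(
    dist_x: MatchedTruncNorm,
    dist_y: MatchedTruncNorm,
    rho: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) with the two matched marginals and Gaussian-copula rho."""
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return dist_x.ppf(stats.norm.cdf(z1)), dist_y.ppf(stats.norm.cdf(z2))


def calibrate_copula_rho(
    dist_x: MatchedTruncNorm,
    dist_y: MatchedTruncNorm,
    statistic: Callable[[np.ndarray, np.ndarray], float],
    target: float,
) -> float:
    """Find rho so that E[statistic(x, y)] hits ``target``.

    The expectation is approximated on a fixed internal normal design, so the
    result does not depend on any user seed. The statistic must be monotone in
    rho over [-0.999, 0.999]; if the target lies outside the attainable range
    the nearest endpoint is returned.
    """
    z1, z2 = _calibration_normals()
    u1 = stats.norm.cdf(z1)
    x = dist_x.ppf(u1)

    def value(rho: float) -> float:
        zz = rho * z1 + np.sqrt(1 - rho**2) * z2
        y = dist_y.ppf(stats.norm.cdf(zz))
        return statistic(x, y)

    lo, hi = value(-0.999), value(0.999)
    sign = 1.0 if hi >= lo else -1.0
    if sign * (target - lo) <= 0:
        return -0.999
    if sign * (target - hi) >= 0:
        return 0.999
    return optimize.brentq(lambda r: value(r) - target, -0.999, 0.999, xtol=1e-6)
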